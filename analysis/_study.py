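"""Shared access to the synthetic study set for the analysis drivers."""

import json
import runpy
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
MANIFEST = ROOT / "results" / "study_manifest.json"


def ensure_study() -> dict:
    """Return the study manifest, regenerating the study set whenever the
    manifest or any file it references is missing."""
    if MANIFEST.exists():
        manifest = json.loads(MANIFEST.read_text())
        paths = [p for ps in manifest["structures"].values() for p in ps]
        paths += [manifest["alignment"]["path"], manifest["charge_sequences"],
                  manifest["tree"]["path"]]
        if all(Path(p).exists() for p in paths):
            return manifest
    runpy.run_path(str(ROOT / "analysis" / "01_simulate_study.py"),
                   run_name="__main__")
    return json.loads(MANIFEST.read_text())
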