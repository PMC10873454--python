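#!/usr/bin/env python
"""Acidic/basic charge profiles, whole protein and surface-restricted.

Computes SASA and relative-SASA surface flags (threshold 0.25) for every
study structure, then counts acidic (D, E) and basic (R, K, H) residues in
both scopes and contrasts the counts and the acidic/basic ratio between
clusters.  Also profiles the two planted charge-composition sequences as a
sequence-only check (40/20 acidic/basic vs 25/30)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import ensure_study

import pandas as pd

from xynrin.pipeline import PipelineConfig, run_pipeline
from xynrin.structio import read_fasta
from xynrin.surface import charge_profile

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    manifest = ensure_study()

    for rid, seq in read_fasta(manifest["charge_sequences"]):
        prof = charge_profile(seq)["whole"]
        print(f"{rid}: {prof.n_acidic} acidic, {prof.n_basic} basic, "
              f"ratio {prof.acidic_basic_ratio:.2f}")

    config = PipelineConfig(structures=manifest["structures"],
                            out_dir=str(RESULTS / "charge"),
                            n_sphere_points=480, run_surface=True)
    report = run_pipeline(config)
    charge = pd.read_csv(RESULTS / "charge" / "charge_profiles.tsv", sep="\t")
    print()
    print(charge.groupby(["scope", "cluster"])[["n_acidic", "n_basic"]].mean())
    for scope, contrasts in report["stages"]["charge"].items():
        for metric, c in contrasts.items():
            pw = c["pairwise"][0]
            tag = "SIGNIFICANT" if pw["significant"] else "ns"
            print(f"{scope:>8} {metric:>18}: p={pw['t_pvalue']:.4f} {tag}")
    print(f"\nfull tables under {RESULTS / 'charge'}")


if __name__ == "__main__":
    main()
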