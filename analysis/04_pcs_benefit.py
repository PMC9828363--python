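#!/usr/bin/env python
"""Paired with/without-PCS refinement comparison: 20 seeded replicates of a
perturbed two-helix junction, refined with local geometry restraints alone
or together with four-metal PCS restraints. Writes per-replicate angles and
a summary to results/pcs_benefit/."""

from pathlib import Path

import numpy as np
import pandas as pd

from parashift.experiments import with_without_pcs_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "pcs_benefit"
SEED = 101


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    res = with_without_pcs_experiment(n_seeds=20, seed=SEED)

    pd.DataFrame({
        "replicate": np.arange(1, len(res.angles_with) + 1),
        "start_angle_deg": res.start_angles,
        "angle_with_pcs_deg": res.angles_with,
        "angle_without_pcs_deg": res.angles_without,
    }).to_csv(OUT / "angles.tsv", sep="\t", index=False, float_format="%.3f")

    summary = pd.DataFrame([
        {"condition": "with_pcs",
         "angle_mean_deg": float(np.mean(res.angles_with)),
         "angle_sd_deg": res.angle_sd_with,
         "bundle_pairwise_rmsd_A": res.rmsd_with},
        {"condition": "without_pcs",
         "angle_mean_deg": float(np.mean(res.angles_without)),
         "angle_sd_deg": res.angle_sd_without,
         "bundle_pairwise_rmsd_A": res.rmsd_without},
    ])
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False, float_format="%.3f")

    print(f"true angle: {res.true_angle:.0f}°, {len(res.angles_with)} replicates")
    print(f"  with PCS:    {np.mean(res.angles_with):6.1f}° ± {res.angle_sd_with:4.1f}°, "
          f"bundle RMSD {res.rmsd_with:.2f} Å")
    print(f"  without PCS: {np.mean(res.angles_without):6.1f}° ± {res.angle_sd_without:4.1f}°, "
          f"bundle RMSD {res.rmsd_without:.2f} Å")
    print("PCS restraints shrink both the angle scatter and the bundle spread."
          if res.angle_sd_with < res.angle_sd_without
          and res.rmsd_with < res.rmsd_without
          else "WARNING: expected ordering not observed")
    print(f"wrote {OUT}/angles.tsv and summary.tsv")


if __name__ == "__main__":
    main()
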