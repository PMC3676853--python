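#!/usr/bin/env python
"""Fit GNM and ANM B-factor predictions to the synthetic experiment.

For each conformer, computes unscaled mean-square fluctuations with both
network models, fits the k_BT/γ scale by least squares through the origin,
and reports the Pearson correlation with the generated B-factor column —
the standard check that an elastic network captures a structure's
crystallographic mobility profile.  Run 01_simulate_conformers.py first.
"""

from pathlib import Path

import pandas as pd

import enmpair as ep

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for form in ("open", "closed"):
        s = ep.read_calpha(RESULTS / "synthetic" / f"{form}.pdb")
        g = ep.build_kirchhoff(s, ep.DEFAULT_GNM_CUTOFF)
        a = ep.build_hessian(s, ep.DEFAULT_ANM_CUTOFF)
        for kind, msf in (("GNM", ep.gnm_msf(g).msf), ("ANM", ep.anm_msf(a).msf)):
            fit = ep.fit_scale(msf, s.exp_bfactor)
            rows.append({
                "conformer": form,
                "model": kind,
                "kbt_over_gamma_A2": round(fit.scale_kbt_over_gamma, 4),
                "pearson_r": round(fit.pearson_r, 4),
                "n_residues": fit.n_residues,
            })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "bfactor_fits.csv", index=False)
    print(table.to_string(index=False))
    gnm_open = table[(table.conformer == "open") & (table.model == "GNM")].iloc[0]
    print(f"\nGNM on the open form recovers k_BT/γ ≈ "
          f"{gnm_open.kbt_over_gamma_A2} Å² (truth 5.64 Å²). The synthetic "
          "B column is generated from the GNM, so the GNM fit recovers the "
          "truth and the ANM correlates less — on real crystallographic data "
          "the two models perform comparably.")


if __name__ == "__main__":
    main()
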