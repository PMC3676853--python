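#!/usr/bin/env python
"""Conformer comparison: difference-distance map, cross-correlations, angle.

The difference-distance map should be near zero inside each domain (rigid
bodies) and exceed ±1.5 Å across the hinge; the all-mode GNM
cross-correlation map shows the two domains as anticorrelated blocks; the
two-stage superposition recovers the generator's 41.3° rotation.
Run 01_simulate_conformers.py first.
"""

import json
from pathlib import Path

import numpy as np

import enmpair as ep
from enmpair.enm import write_matrix_csv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    truth = json.loads((RESULTS / "synthetic" / "labels.json").read_text())
    open_f = ep.read_calpha(RESULTS / "synthetic" / "open.pdb")
    closed_f = ep.read_calpha(RESULTS / "synthetic" / "closed.pdb")
    pairing = ep.pair_residues(open_f, closed_f)

    ddm = ep.difference_distance(open_f, closed_f, pairing, threshold=1.5)
    write_matrix_csv(ddm.delta, RESULTS / "difference_distance.csv")
    np.savetxt(RESULTS / "difference_distance_classes.csv", ddm.classes,
               delimiter=",", fmt="%d")
    ia = np.asarray(truth["domain_a_resnums"]) - 1
    ib = np.asarray(truth["domain_b_resnums"]) - 1
    intra = max(np.abs(ddm.delta[np.ix_(ia, ia)]).max(),
                np.abs(ddm.delta[np.ix_(ib, ib)]).max())
    cross = np.abs(ddm.delta[np.ix_(ia, ib)])

    cmap = ep.cross_correlation(ep.build_kirchhoff(open_f, ep.DEFAULT_GNM_CUTOFF))
    write_matrix_csv(cmap.c, RESULTS / "cross_correlation_open.csv")
    block = cmap.c[np.ix_(ia, ib)]

    rot = ep.rotation_angle(open_f, closed_f, pairing,
                            [(truth["domain_a_resnums"][0], truth["domain_a_resnums"][-1])],
                            [(truth["domain_b_resnums"][0], truth["domain_b_resnums"][-1])])
    summary = {
        "max_intra_domain_ddm_A": float(intra),
        "max_cross_domain_ddm_A": float(cross.max()),
        "fraction_cross_pairs_beyond_1p5A": float((cross >= 1.5).mean()),
        "mean_interdomain_cross_correlation": float(block.mean()),
        "rotation_angle_deg": rot.angle_deg,
        "true_angle_deg": truth["true_angle_deg"],
        "rmsd_fixed_A": rot.rmsd_fixed,
    }
    with open(RESULTS / "maps_rotation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"difference-distance: intra-domain max {intra:.2e} Å (rigid), "
          f"{summary['fraction_cross_pairs_beyond_1p5A']:.0%} of cross-domain pairs "
          f"move ≥ 1.5 Å")
    print(f"mean inter-domain cross-correlation {block.mean():+.3f} "
          "(anticorrelated domains)")
    print(f"recovered rotation angle {rot.angle_deg:.6f}° "
          f"(truth {truth['true_angle_deg']}°)")


if __name__ == "__main__":
    main()
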