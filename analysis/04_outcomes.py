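#!/usr/bin/env python
"""Delta connectivity of the interaction networks vs clinical outcomes.

For each significant sleep-by-group interaction network (from 03),
summarises each subject's network dynamics as Delta = AS - QS and
correlates it (two-tailed Spearman) with the neurological composites
C1/C2 and the four neurocognitive scores, BH-FDR corrected within each
assessment family. Also reproduces the composite scores from the raw
synthetic neurological items via PCA as a cross-check.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from neonet import correlate_outcomes, delta_connectivity, pca_composites
from neonet.io import load_connectivity_h5, load_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = load_study(ROOT / "scratch" / "study")
    matrices, _ = load_connectivity_h5(ROOT / "scratch" / "connectivity.h5")
    table = pd.read_csv(ROOT / "results" / "03_nbs.csv")
    edges = json.loads((ROOT / "results" / "03_network_edges.json").read_text())

    sig = table.query("contrast == 'interaction' and p_fwe < 0.05")
    if sig.empty:
        print("no significant interaction network; nothing to correlate")
        return

    deltas = {}
    for _, row in sig.iterrows():
        key = f"interaction_{row.band}_{row.direction}"
        net = [tuple(e) for e in edges[key]]
        deltas[key] = [delta_connectivity(matrices[(s, "AS", row.band)],
                                          matrices[(s, "QS", row.band)], net)
                       for s in study.subjects]
    deltas = pd.DataFrame(deltas, index=pd.Index(study.subjects,
                                                 name="subject"))

    report = correlate_outcomes(deltas, study.outcomes)
    report.to_csv(ROOT / "results" / "04_outcome_correlations.csv",
                  index=False)
    print(report.round(4).to_string(index=False))

    # cross-check: PCA of the synthetic neurological items reproduces
    # the C1/C2 composites carried by the outcome table
    scores, _ = pca_composites(study.hnne_items)
    for c in ("C1", "C2"):
        r = np.corrcoef(scores[c], study.outcomes[c])[0, 1]
        print(f"PCA-reproduced {c} vs generated {c}: |r| = {abs(r):.3f}")


if __name__ == "__main__":
    main()
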