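#!/usr/bin/env python
"""Sensor preprocessing, source reconstruction, connectivity, and the
edge-fidelity mask.

Reads the study written by 01, runs the standard chain per recording
(0.4-45 Hz prefilter, average montage, band filtering, equidistant
epochs), reconstructs noise-normalized source signals, collapses them to
fidelity-weighted parcel signals, computes debiased-wPLI matrices per
subject/state/band, and builds the per-band edge-fidelity mask. All
matrices go to scratch/connectivity.h5; a mask summary goes to results/.
"""
import time
from pathlib import Path

import numpy as np
import pandas as pd

from neonet import (apply_inverse, apply_mask, collapse_parcels,
                    compute_fidelity_weights, connectivity_matrix,
                    fidelity_mask, make_inverse)
from neonet.io import load_study, save_connectivity_h5
from neonet.pipeline import preprocess_recording

ROOT = Path(__file__).resolve().parents[1]

FIDELITY_ITER = 25  # desk-scale stand-in for the production 500


def main() -> None:
    t0 = time.time()
    study = load_study(ROOT / "scratch" / "study")
    cfg = study.config
    lf, parc = study.lead_field, study.parcellation

    inv = make_inverse(lf, None, lam=1.0 / 9.0)
    parc.fidelity_weights = compute_fidelity_weights(lf, inv, parc,
                                                     n_iter=50,
                                                     seed=cfg.seed + 1)
    matrices = {}
    for (subj, state), rec in study.recordings.items():
        per_band = preprocess_recording(rec, cfg.bands,
                                        target_rate=cfg.sampling_rate,
                                        epoch_windows=cfg.epoch_windows,
                                        window_length=cfg.window_length,
                                        state=state)
        for band_name, windows in per_band.items():
            src = [collapse_parcels(apply_inverse(inv, w), parc)
                   for w in windows]
            matrices[(subj, state, band_name)] = connectivity_matrix(
                src, cfg.sampling_rate, band=band_name, state=state,
                subject=subj, trim_seconds=1.0)

    masks, rows = {}, []
    for band in cfg.bands:
        m = fidelity_mask(lf, inv, parc, band, cfg.sampling_rate,
                          n_iter=FIDELITY_ITER, seed=cfg.seed + 2)
        masks[band.name] = m
        rows.append(dict(band=band.name, n_excluded=m.n_excluded,
                         n_retained=m.n_retained,
                         threshold=round(m.threshold, 4)))
    masked = {k: apply_mask(cm, masks[k[2]]) for k, cm in matrices.items()}

    save_connectivity_h5(ROOT / "scratch" / "connectivity.h5", masked, masks)
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "results" / "02_mask_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"{len(masked)} matrices written ({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    main()
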