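"""On-disk layout for studies and results.

Recordings are stored as flat binary arrays (``.npy``) with a JSON
sidecar carrying sampling rate, channel names, and sleep-state
annotations; head model, parcellation, outcomes and atlas as CSV; the
configuration as JSON. EDF recordings can be ingested through MNE.
Connectivity matrices and masks can be exported to HDF5
(``wpli/<subject>/<state>/<band>``, ``mask/<band>``).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BandSpec, StudyConfig
from .connectivity import ConnectivityMatrix, EdgeMask
from .preprocess import SensorRecording
from .source_model import LeadField, Parcellation


def save_recording(rec: SensorRecording, path: str | Path) -> Path:
    """Write a recording as `<path>.npy` + `<path>.json` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = dict(sampling_rate=rec.sampling_rate,
                   channel_names=rec.channel_names,
                   annotations=[list(a) for a in rec.annotations])
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def load_recording(path: str | Path) -> SensorRecording:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return SensorRecording(
        data=data, sampling_rate=meta["sampling_rate"],
        channel_names=meta["channel_names"],
        annotations=[(s, float(a), float(b))
                     for s, a, b in meta["annotations"]])


def read_edf(path: str | Path,
             annotations: list[tuple[str, float, float]] | None = None
             ) -> SensorRecording:
    """Read an EDF recording (via MNE) into a SensorRecording.

    Sleep-state annotations are taken from the EDF's own annotations
    when their descriptions are state labels, or passed explicitly.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if annotations is None:
        annotations = [(str(d), float(o), float(o + du)) for d, o, du in
                       zip(raw.annotations.description, raw.annotations.onset,
                           raw.annotations.duration) if du > 0]
    return SensorRecording(data=raw.get_data(), sampling_rate=raw.info["sfreq"],
                           channel_names=list(raw.ch_names),
                           annotations=annotations)


def save_head_model(lf: LeadField, parc: Parcellation, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(lf.matrix).to_csv(outdir / "lead_field.csv", index=False)
    src = pd.DataFrame(dict(parcel=parc.assignment,
                            weight=parc.fidelity_weights))
    if lf.source_positions is not None:
        src[["x", "y", "z"]] = lf.source_positions
    src.to_csv(outdir / "sources.csv", index_label="source")
    parcels = pd.DataFrame(dict(name=parc.names, region=parc.region_label))
    if parc.centroids is not None:
        parcels[["cx", "cy", "cz"]] = parc.centroids
    parcels.to_csv(outdir / "parcels.csv", index_label="parcel")


def load_head_model(outdir: str | Path) -> tuple[LeadField, Parcellation]:
    outdir = Path(outdir)
    G = pd.read_csv(outdir / "lead_field.csv").to_numpy(float)
    src = pd.read_csv(outdir / "sources.csv", index_col="source")
    parcels = pd.read_csv(outdir / "parcels.csv", index_col="parcel")
    pos = (src[["x", "y", "z"]].to_numpy(float)
           if {"x", "y", "z"}.issubset(src.columns) else None)
    cen = (parcels[["cx", "cy", "cz"]].to_numpy(float)
           if {"cx", "cy", "cz"}.issubset(parcels.columns) else None)
    lf = LeadField(matrix=G, source_positions=pos)
    parc = Parcellation(assignment=src["parcel"].to_numpy(int),
                        n_parcels=len(parcels),
                        region_label=list(parcels["region"]),
                        centroids=cen, names=list(parcels["name"]),
                        fidelity_weights=src["weight"].to_numpy(float))
    return lf, parc


def save_study(study, outdir: str | Path) -> Path:
    """Write a SyntheticStudy to a directory layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(study.config.to_dict(), indent=1, default=str))
    save_head_model(study.lead_field, study.parcellation, outdir / "model")
    for (subj, state), rec in study.recordings.items():
        save_recording(rec, outdir / "recordings" / f"{subj}_{state}")
    study.outcomes.to_csv(outdir / "outcomes.csv")
    study.hnne_items.to_csv(outdir / "hnne_items.csv")
    study.atlas.to_csv(outdir / "atlas.csv", index=False)
    meta = dict(subjects=study.subjects, groups=study.groups.tolist(),
                planted_edges={k: [list(e) for e in v] for k, v in
                               study.truth["planted_edges"].items()})
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_config(path: str | Path) -> StudyConfig:
    d = json.loads(Path(path).read_text())
    d["bands"] = tuple(BandSpec(**b) for b in d["bands"])
    if d.get("phase_lag") is not None:
        d["phase_lag"] = float(d["phase_lag"])
    return StudyConfig(**d)


def load_study(outdir: str | Path):
    """Reload a study written by :func:`save_study`.

    The per-subject coupling truth is not persisted; ``truth`` carries
    the planted edge sets only.
    """
    from .synthetic import SyntheticStudy

    outdir = Path(outdir)
    config = load_config(outdir / "config.json")
    lf, parc = load_head_model(outdir / "model")
    meta = json.loads((outdir / "cohort.json").read_text())
    subjects = meta["subjects"]
    groups = np.asarray(meta["groups"], dtype=int)
    recordings = {}
    for subj in subjects:
        for state in ("AS", "QS"):
            recordings[(subj, state)] = load_recording(
                outdir / "recordings" / f"{subj}_{state}")
    outcomes = pd.read_csv(outdir / "outcomes.csv", index_col="subject")
    items = pd.read_csv(outdir / "hnne_items.csv", index_col="subject")
    atlas = pd.read_csv(outdir / "atlas.csv")
    truth = dict(planted_edges={k: [tuple(e) for e in v] for k, v in
                                meta["planted_edges"].items()})
    return SyntheticStudy(config=config, lead_field=lf, parcellation=parc,
                          recordings=recordings, subjects=subjects,
                          groups=groups, truth=truth, outcomes=outcomes,
                          hnne_items=items, atlas=atlas)


def save_connectivity_h5(path: str | Path,
                         matrices: dict[tuple[str, str, str], ConnectivityMatrix],
                         masks: dict[str, EdgeMask] | None = None) -> Path:
    """HDF5 export: datasets ``wpli/<subject>/<state>/<band>`` and
    ``mask/<band>``."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for (subj, state, band), cm in matrices.items():
            f.create_dataset(f"wpli/{subj}/{state}/{band}", data=cm.values)
        for band, m in (masks or {}).items():
            f.create_dataset(f"mask/{band}", data=m.mask.astype(np.uint8))
    return path


def load_connectivity_h5(path: str | Path):
    import h5py

    matrices: dict[tuple[str, str, str], ConnectivityMatrix] = {}
    masks: dict[str, EdgeMask] = {}
    with h5py.File(path, "r") as f:
        if "wpli" in f:
            for subj in f["wpli"]:
                for state in f[f"wpli/{subj}"]:
                    for band in f[f"wpli/{subj}/{state}"]:
                        matrices[(subj, state, band)] = ConnectivityMatrix(
                            values=f[f"wpli/{subj}/{state}/{band}"][()],
                            band=band, state=state, subject=subj)
        if "mask" in f:
            for band in f["mask"]:
                masks[band] = EdgeMask(mask=f[f"mask/{band}"][()].astype(bool))
    return matrices, masks
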