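"""Synthetic study generator.

Builds complete two-group (46 exposed vs 61 control), two-sleep-state
cohorts whose statistical structure matches the modelled study: phase
coupling planted on known edge sets with state- and group-dependent
strength, sensor recordings obtained by projecting parcel signals
through a toy spherical head model at a fixed SNR, outcome scores linked
to the planted connectivity dynamics through a Gaussian copula, and a
layer-resolved neuronal-density atlas with an optional planted contrast
in the network regions.

Planted coupling is edge-exact: every planted edge owns a private
band-limited driver shared (with a constant quarter-cycle lag) by its
two endpoint parcels, so phase coupling exists on exactly the planted
edges, not on every pair inside a connected component.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import STATES, BandSpec, InvalidConfigError, StudyConfig
from .preprocess import SensorRecording
from .signals import band_limited_noise, phase_rotate
from .source_model import LeadField, Parcellation

#: relative amplitude of each band component in the broadband mixture,
#: mimicking the decaying EEG spectrum
BAND_AMPLITUDES = {"low_delta": 1.0, "high_delta": 0.7, "theta": 0.45,
                   "alpha": 0.3}

#: layer-wise mean neuronal densities (neurons per mm^3), molecular layer
#: sparse, granular layers dense — magnitudes typical of infant cortex
ATLAS_LAYER_MEANS = (20e3, 90e3, 70e3, 110e3, 55e3, 45e3)
ATLAS_REGION_CV = 0.12  # region-to-region coefficient of variation


@dataclass
class SyntheticStudy:
    """A complete generated study with its ground truth."""

    config: StudyConfig
    lead_field: LeadField
    parcellation: Parcellation
    recordings: dict[tuple[str, str], SensorRecording]  # (subject, state)
    subjects: list[str]
    groups: np.ndarray  # 1 = AED (exposed), 0 = HC (control)
    truth: dict
    outcomes: pd.DataFrame
    hnne_items: pd.DataFrame
    atlas: pd.DataFrame


def _fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return radius * np.column_stack([np.sin(phi) * np.cos(theta),
                                     np.sin(phi) * np.sin(theta),
                                     np.cos(phi)])


def _region_of(centroid: np.ndarray) -> str:
    x, y, _z = centroid
    if x >= 0.33:
        return "frontal"
    if x <= -0.33:
        return "occipital"
    return "temporal" if abs(y) >= 0.5 else "central"


def generate_head_model(config: StudyConfig) -> tuple[LeadField, Parcellation]:
    """Toy head model: lead field plus parcellation with centroids.

    ``mixing="identity"`` returns an unmixed model (sensors = sources)
    for oracle tests; ``mixing="spherical"`` places sensors just outside
    a unit sphere of sources and uses a smooth inverse-square distance
    gain, giving realistic cross-talk between neighbouring sources.
    """
    if config.n_parcels > config.n_sources:
        raise InvalidConfigError("more parcels than sources")
    if config.n_sensors < 8 and config.mixing == "spherical":
        raise InvalidConfigError("spherical model needs >= 8 sensors")
    src_pos = _fibonacci_sphere(config.n_sources, 1.0)
    if config.mixing == "identity":
        if config.n_sensors != config.n_sources:
            raise InvalidConfigError("identity mixing needs n_sensors == n_sources")
        G = np.eye(config.n_sources)
    else:
        sens_pos = _fibonacci_sphere(config.n_sensors, 1.15)
        d2 = ((sens_pos[:, None, :] - src_pos[None, :, :]) ** 2).sum(-1)
        G = 1.0 / (0.15 + d2)
        G /= np.linalg.norm(G, axis=0, keepdims=True).mean()
    # parcels: nearest of n_parcels quasi-uniform centroid seeds, then
    # empty parcels (possible for small source counts) grab their
    # nearest source
    seeds = _fibonacci_sphere(config.n_parcels, 1.0)
    d2p = ((src_pos[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
    assignment = d2p.argmin(axis=1)
    for p in range(config.n_parcels):
        if not np.any(assignment == p):
            order = np.argsort(d2p[:, p])
            for s in order:
                if np.sum(assignment == assignment[s]) > 1:
                    assignment[s] = p
                    break
    centroids = np.vstack([src_pos[assignment == p].mean(axis=0)
                           for p in range(config.n_parcels)])
    regions = [_region_of(c) for c in centroids]
    lf = LeadField(matrix=G, source_positions=src_pos,
                   source_orientations=src_pos.copy())
    parc = Parcellation(assignment=assignment, n_parcels=config.n_parcels,
                        region_label=regions, centroids=centroids)
    return lf, parc


def generate_coupled_pair(n_samples: int, sampling_rate: float,
                          band: BandSpec, lag: float, coupling: float,
                          noise_sd: float = 0.0,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Two band-limited signals with controlled phase coupling.

    Construction: a shared band-limited driver plus independent
    band-limited noise, mixed as ``sqrt(c) * common + sqrt(1-c) *
    private``; the lag is a constant phase rotation of the driver in the
    second signal. At ``coupling=1`` with a non-trivial lag the
    population debiased wPLI approaches 1; at ``coupling=0`` the signals
    are independent.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    band.validate(sampling_rate)
    if coupling == 1.0 and abs(np.sin(lag)) < 1e-9:
        warnings.warn("lag = 0 mod pi with full coupling: imaginary "
                      "cross-spectrum is zero, wPLI will be 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    common = band_limited_noise(n_samples, sampling_rate, band, rng)
    p1 = band_limited_noise(n_samples, sampling_rate, band, rng)
    p2 = band_limited_noise(n_samples, sampling_rate, band, rng)
    a, b = np.sqrt(coupling), np.sqrt(1.0 - coupling)
    x = a * common + b * p1
    y = a * phase_rotate(common, lag) + b * p2
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n_samples)
        y = y + noise_sd * rng.standard_normal(n_samples)
    return x, y


def _random_connected_edges(n_parcels: int, n_edges: int,
                            rng: np.random.Generator,
                            exclude: set | None = None,
                            exclude_nodes: set | None = None) -> list[tuple[int, int]]:
    """A compact random connected edge set avoiding `exclude`d edges.

    Edges are drawn over the smallest node set that can host them plus
    one spare node, giving a dense subnetwork (like the focal cortical
    clusters the analysis targets) that stays connected even when only
    part of it is recovered.
    """
    exclude = exclude or set()
    exclude_nodes = exclude_nodes or set()
    m = 2
    while m * (m - 1) // 2 < n_edges:
        m += 1
    m = min(m, n_parcels)
    if m * (m - 1) // 2 < n_edges + len(exclude):
        m = n_parcels
    if m * (m - 1) // 2 < n_edges:
        raise InvalidConfigError("too many planted edges for parcel count")
    avail = np.array(sorted(set(range(n_parcels)) - exclude_nodes))
    if avail.size < m:
        raise InvalidConfigError("not enough free parcels for planted edges")
    for _ in range(1000):
        nodes = rng.choice(avail, size=m, replace=False)
        cand = [(min(int(a), int(b)), max(int(a), int(b)))
                for k, a in enumerate(nodes) for b in nodes[k + 1:]]
        cand = [e for e in cand if e not in exclude]
        if len(cand) < n_edges:
            continue
        pick = rng.choice(len(cand), size=n_edges, replace=False)
        edges = [cand[i] for i in pick]
        # connectivity check (union-find)
        parent = {n: n for e in edges for n in e}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in edges:
            parent[find(a)] = find(b)
        if len({find(n) for n in parent}) == 1:
            return edges
    raise InvalidConfigError("cannot place planted edges")


def _planted_coupling(config: StudyConfig, group: int, state: str,
                      which: str, jitter: float) -> float:
    """Coupling fraction for a planted edge set, by group and state.

    Interaction edges: exposed group is AS-dominant, control group
    QS-dominant (opposite-signed AS-QS difference). Sleep edges:
    AS-dominant in both groups.
    """
    k0 = config.coupling_strength
    if which == "interaction":
        e = config.interaction_effect
        sign = 1.0 if (group == 1) == (state == "AS") else -1.0
    else:  # sleep
        e = config.sleep_effect
        sign = 1.0 if state == "AS" else -1.0
    return float(np.clip(k0 * (1.0 + sign * e) + jitter, 0.0, 1.0))


def _parcel_signals(config: StudyConfig, couplings: dict, n_samples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Broadband parcel signals with coupling planted in one band.

    ``couplings`` maps edge -> coupling fraction (within the planted
    band). Each planted edge owns one driver; an endpoint of degree d
    receives each of its drivers with variance k/d so coupling stays
    edge-supported.
    """
    P = config.n_parcels
    total = np.zeros((P, n_samples))
    for bspec in config.bands:
        amp = BAND_AMPLITUDES.get(bspec.name, 0.5)
        comp = np.vstack([band_limited_noise(n_samples, config.sampling_rate,
                                             bspec, rng) for _ in range(P)])
        if bspec.name == config.planted_band and couplings:
            degree = np.zeros(P)
            for (i, j) in couplings:
                degree[i] += 1
                degree[j] += 1
            shared = np.zeros((P, n_samples))
            shared_var = np.zeros(P)
            for (i, j), k in couplings.items():
                if k <= 0:
                    continue
                drv = band_limited_noise(n_samples, config.sampling_rate,
                                         bspec, rng)
                shared[i] += np.sqrt(k / degree[i]) * drv
                shared[j] += np.sqrt(k / degree[j]) * phase_rotate(
                    drv, config.phase_lag)
                shared_var[i] += k / degree[i]
                shared_var[j] += k / degree[j]
            priv = np.sqrt(np.clip(1.0 - shared_var, 0.0, 1.0))
            comp = shared + priv[:, None] * comp
        total += amp * comp
    return total


def _sensor_projection(parcel_sig: np.ndarray, lf: LeadField,
                       parc: Parcellation, snr_db: float,
                       rng: np.random.Generator) -> np.ndarray:
    src = parcel_sig[parc.assignment]
    sensors = lf.matrix @ src
    sig_power = np.mean(sensors ** 2)
    noise_power = sig_power / (10.0 ** (snr_db / 10.0))
    return sensors + np.sqrt(noise_power) * rng.standard_normal(sensors.shape)


def _copula_scores(delta: np.ndarray, target_rho: float, mean: float,
                   sd: float, rng: np.random.Generator) -> np.ndarray:
    """Scores with Spearman correlation ~ `target_rho` against `delta`.

    Gaussian copula: delta is rank-transformed to normal scores, a
    latent normal is mixed at the Pearson level ``2 sin(pi * rho / 6)``
    that yields the requested Spearman rho, then scaled to the score
    units.
    """
    n = delta.size
    z = stats.norm.ppf(stats.rankdata(delta) / (n + 1))
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    latent = r * z + np.sqrt(max(0.0, 1.0 - r ** 2)) * rng.standard_normal(n)
    return mean + sd * latent


def generate_cohort(config: StudyConfig) -> SyntheticStudy:
    """Generate a full synthetic study from a configuration.

    Deterministic per config: the same config (including seed) yields
    bit-identical recordings, outcomes, and atlas.
    """
    rng = np.random.default_rng(config.seed)
    lf, parc = generate_head_model(config)
    n_samples = int(round(config.state_duration * config.sampling_rate))
    need = int(round(config.epoch_windows * config.window_length
                     * config.sampling_rate))
    if n_samples < need:
        raise InvalidConfigError("recording shorter than the epoch plan")

    if config.planted_edges is not None:
        planted = {k: [tuple(e) for e in v]
                   for k, v in config.planted_edges.items()}
    elif config.coupling_strength == 0.0:
        planted = {}
    else:
        inter = _random_connected_edges(config.n_parcels,
                                        config.n_planted_edges, rng)
        sleep = _random_connected_edges(
            config.n_parcels, config.n_planted_edges, rng,
            exclude_nodes={p for e in inter for p in e})
        planted = {"interaction": inter, "sleep": sleep}
    for edges in planted.values():
        for i, j in edges:
            if not (0 <= i < config.n_parcels and 0 <= j < config.n_parcels
                    and i != j):
                raise InvalidConfigError(f"invalid planted edge ({i}, {j})")

    subjects = [f"S{k:03d}" for k in range(config.n_subjects)]
    groups = np.array([1] * config.n_group_a + [0] * config.n_group_b)

    recordings: dict[tuple[str, str], SensorRecording] = {}
    coupling_truth: dict[str, dict[str, dict[tuple[int, int], float]]] = {}
    delta_true = np.zeros(config.n_subjects)
    for s_idx, subj in enumerate(subjects):
        coupling_truth[subj] = {}
        per_state_mean = {}
        for state in STATES:
            # state-specific subject variability, so the AS-QS coupling
            # difference itself varies between subjects
            jitter = float(rng.normal(0.0, config.subject_sd))
            couplings: dict[tuple[int, int], float] = {}
            for which, edges in planted.items():
                for e in edges:
                    couplings[e] = _planted_coupling(config, groups[s_idx],
                                                     state, which, jitter)
            coupling_truth[subj][state] = dict(couplings)
            parcel_sig = _parcel_signals(config, couplings, n_samples, rng)
            sensors = _sensor_projection(parcel_sig, lf, parc,
                                         config.snr_db, rng)
            recordings[(subj, state)] = SensorRecording(
                data=sensors, sampling_rate=config.sampling_rate,
                annotations=[(state, 0.0, n_samples / config.sampling_rate)])
            inter_edges = planted.get("interaction", [])
            if inter_edges:
                per_state_mean[state] = float(np.mean(
                    [couplings[e] for e in inter_edges]))
        if per_state_mean:
            delta_true[s_idx] = per_state_mean["AS"] - per_state_mean["QS"]

    outcomes, items = _generate_outcomes(config, subjects, delta_true, rng)
    atlas = generate_atlas(config, parc,
                           planted.get("interaction", []), rng)

    truth = dict(planted_edges=planted, couplings=coupling_truth,
                 delta=pd.Series(delta_true, index=subjects))
    return SyntheticStudy(config=config, lead_field=lf, parcellation=parc,
                          recordings=recordings, subjects=subjects,
                          groups=groups, truth=truth, outcomes=outcomes,
                          hnne_items=items, atlas=atlas)


def _generate_outcomes(config: StudyConfig, subjects: list[str],
                       delta_true: np.ndarray, rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome scores; C2 and fine_motor carry the planted correlation.

    The neurological composites C1/C2 are reproduced from a synthetic
    neurological item table via a two-factor model so that PCA on the
    items recovers them.
    """
    n = len(subjects)
    rho = config.outcome_effect
    has_effect = np.abs(delta_true).max() > 0
    x = delta_true if has_effect else rng.standard_normal(n)
    C1 = _copula_scores(x, 0.0, 0.0, 1.0, rng)
    C2 = _copula_scores(x, -rho if has_effect else 0.0, 0.0, 1.0, rng)
    fine_motor = _copula_scores(x, rho if has_effect else 0.0, 100.0, 15.0, rng)
    cognitive = _copula_scores(x, 0.0, 100.0, 15.0, rng)
    receptive = _copula_scores(x, 0.0, 100.0, 15.0, rng)
    expressive = _copula_scores(x, 0.0, 100.0, 15.0, rng)
    outcomes = pd.DataFrame(
        dict(C1=C1, C2=C2, cognitive=cognitive,
             receptive_language=receptive, expressive_language=expressive,
             fine_motor=fine_motor),
        index=pd.Index(subjects, name="subject"))
    # two-factor neurological item table: 8 items loading on C1/C2 in
    # unequal blocks (5 vs 3) so the principal axes stay identifiable
    n_items = 8
    load1 = np.array([0.8, 0.75, 0.7, 0.65, 0.6, 0.1, 0.1, 0.05])
    load2 = np.array([0.1, 0.05, 0.1, 0.05, 0.1, 0.8, 0.75, 0.7])
    items = (np.outer(C1, load1) + np.outer(C2, load2)
             + 0.3 * rng.standard_normal((n, n_items)))
    item_names = [f"hnne_{k:02d}" for k in range(n_items)]
    items_df = pd.DataFrame(items, index=outcomes.index, columns=item_names)
    return outcomes, items_df


def generate_atlas(config: StudyConfig, parc: Parcellation,
                   network: list[tuple[int, int]],
                   rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Layer-resolved neuronal-density atlas keyed by parcel name.

    Region densities vary log-normally around layer-typical means; when
    ``config.atlas_shift_layer`` is 1-6 and a network is given, that
    layer's density is shifted by ``atlas_shift_sd`` region-level
    standard deviations in the parcels the network touches.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    net_parcels = {p for e in network for p in e}
    rows = []
    sigma = np.sqrt(np.log(1 + ATLAS_REGION_CV ** 2))
    for p in range(parc.n_parcels):
        for layer, mu in zip(range(1, 7), ATLAS_LAYER_MEANS):
            d = mu * np.exp(rng.normal(0.0, sigma)) / np.exp(sigma ** 2 / 2)
            if (layer == config.atlas_shift_layer and p in net_parcels
                    and config.atlas_shift_sd != 0.0):
                d += config.atlas_shift_sd * mu * ATLAS_REGION_CV
            rows.append(dict(region=parc.names[p], layer=layer, density=d))
    return pd.DataFrame(rows)
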