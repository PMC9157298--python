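"""Study configuration: cohort design, frequency bands, and analysis parameters.

The defaults encode the study design this package models: two neonatal
groups (46 drug-exposed vs 61 control infants), two sleep states per
subject (active sleep AS and quiet sleep QS), four frequency bands of
interest, 19 scalp sensors, and a cortical parcellation with 58 regions.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with a name and pass-band edges in Hz."""

    name: str
    low: float
    high: float

    def validate(self, sampling_rate: float) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high, got "
                             f"({self.low}, {self.high})")
        if self.high >= sampling_rate / 2.0:
            raise ValueError(f"band {self.name}: high edge {self.high} Hz "
                             f">= Nyquist {sampling_rate / 2.0} Hz")


#: The four neonatal EEG bands: low delta, high delta, theta, alpha.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("low_delta", 0.4, 1.5),
    BandSpec("high_delta", 1.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
)

STATES: tuple[str, str] = ("AS", "QS")
GROUPS: tuple[str, str] = ("AED", "HC")
REGION_LABELS: tuple[str, ...] = ("frontal", "central", "temporal", "occipital")


class InvalidConfigError(ValueError):
    """Raised when a StudyConfig violates its invariants."""


@dataclass
class StudyConfig:
    """Parameters of a synthetic two-group, two-state connectivity study.

    Attributes
    ----------
    n_group_a, n_group_b
        Subjects in the exposed (AED) and control (HC) groups.
    n_sensors, n_sources, n_parcels
        Sizes of the toy head model: scalp channels, cortical dipoles,
        and cortical parcels.
    sampling_rate
        Sensor sampling rate in Hz (after any decimation).
    epoch_windows, window_length
        Number of equidistant analysis windows per sleep state and their
        length in seconds (defaults 6 x 30 s = 3 min per state).
    recording_length
        Per-state recording duration in seconds; defaults to
        ``epoch_windows * window_length``.
    bands
        Frequency bands of interest; coupling is planted in
        ``planted_band`` only.
    coupling_strength
        Baseline variance fraction carried by planted edge drivers,
        in [0, 1].
    interaction_effect
        Relative state-by-group modulation of the planted coupling: the
        exposed group has coupling ``k*(1+e)`` in AS and ``k*(1-e)`` in
        QS, the control group the opposite, so the AS-QS difference has
        opposite sign in the two groups.
    sleep_effect
        Relative AS-vs-QS modulation on the sleep-main planted edges,
        identical in both groups.
    subject_sd
        Between-subject standard deviation of the coupling fraction
        (biological variability of the planted effect).
    phase_lag
        Constant phase lag (radians) between coupled parcels; the
        quarter cycle default maximises the imaginary cross-spectrum.
    snr_db
        Sensor signal-to-noise ratio of the forward-projected data.
    outcome_effect
        Target Spearman correlation between the planted per-subject
        AS-QS coupling difference and the correlated outcome scores.
    n_planted_edges
        Edges in each planted (connected) network.
    atlas_shift_layer, atlas_shift_sd
        Cytoarchitectonic contrast planted in the atlas: layer index
        (1-6, 0 disables) whose neuronal density is shifted by this many
        region-level standard deviations inside the interaction network.
    mixing
        Head-model construction: ``"spherical"`` (distance-kernel gains
        on a sphere) or ``"identity"`` (sensors = sources, no mixing).
    """

    n_group_a: int = 46
    n_group_b: int = 61
    n_sensors: int = 19
    n_sources: int = 200
    n_parcels: int = 58
    sampling_rate: float = 100.0
    epoch_windows: int = 6
    window_length: float = 30.0
    recording_length: float | None = None
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    planted_band: str = "high_delta"
    coupling_strength: float = 0.6
    interaction_effect: float = 0.3
    sleep_effect: float = 0.3
    subject_sd: float = 0.18
    phase_lag: float = math.pi / 2
    snr_db: float = 10.0
    noise_sd: float = 0.0
    outcome_effect: float = 0.4
    n_planted_edges: int = 10
    planted_edges: dict | None = None
    atlas_shift_layer: int = 3
    atlas_shift_sd: float = 3.0
    mixing: str = "spherical"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def state_duration(self) -> float:
        """Per-state recording duration in seconds."""
        if self.recording_length is not None:
            return float(self.recording_length)
        return self.epoch_windows * self.window_length

    def band(self, name: str) -> BandSpec:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def validate(self) -> None:
        for attr in ("n_group_a", "n_group_b", "n_sensors", "n_sources",
                     "n_parcels", "epoch_windows"):
            if getattr(self, attr) <= 0:
                raise InvalidConfigError(f"{attr} must be positive")
        if self.n_parcels > self.n_sources:
            raise InvalidConfigError(
                f"n_parcels={self.n_parcels} exceeds n_sources={self.n_sources}")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise InvalidConfigError("coupling_strength must be in [0, 1]")
        if not -1.0 <= self.outcome_effect <= 1.0:
            raise InvalidConfigError("outcome_effect must be in [-1, 1]")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.recording_length is not None and (
                self.recording_length < self.epoch_windows * self.window_length):
            raise InvalidConfigError(
                "recording_length shorter than epoch_windows * window_length")
        prev_high = 0.0
        for b in self.bands:
            b.validate(self.sampling_rate)
            if b.low < prev_high:
                raise InvalidConfigError(
                    f"bands must be ordered and non-overlapping at {b.name}")
            prev_high = b.high
        if self.mixing not in ("spherical", "identity"):
            raise InvalidConfigError(f"unknown mixing: {self.mixing!r}")
        if (self.coupling_strength > 0
                and self.planted_band not in {b.name for b in self.bands}):
            raise InvalidConfigError(
                f"planted_band {self.planted_band!r} not among bands")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        return d


@dataclass
class AnalysisParams:
    """Statistical-analysis parameters with study defaults.

    ``t_threshold`` (2.5), ``n_permutations`` (5000), ``alpha`` (0.05)
    drive the network-based statistics; ``fidelity_iterations`` (500) and
    ``fidelity_percentile`` (99) define the edge-fidelity mask;
    ``n_surrogates`` (1000) sizes the cytoarchitectonic null;
    ``min_subgroup`` skips drug subgroups too small for inference.
    """

    t_threshold: float = 2.5
    n_permutations: int = 5000
    alpha: float = 0.05
    fidelity_iterations: int = 500
    fidelity_percentile: float = 99.0
    fidelity_seconds: float | None = None
    apply_fidelity_mask: bool = True
    n_surrogates: int = 1000
    inverse_lambda: float | None = None
    fidelity_weight_iterations: int = 100
    min_subgroup: int = 5
    trim_seconds: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)
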