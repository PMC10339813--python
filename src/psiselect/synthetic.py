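"""Surrogate two-group recordings and planted-feature tables.

The clinical recordings this kind of analysis targets are rarely shareable,
so the package ships a generator that emulates the *statistical design* of
a two-group resting-state study: two cohorts of multichannel epochs whose
pairwise phase coupling differs by group and by frequency band.  The
default preset mirrors a 16-channel, 1024 Hz, 10-s-epoch design with 180
epochs per group, with the "patient" group (A) coupled more weakly than
the control group (B), most distinctly in the alpha/beta/gamma bands.

Signal model per channel and band:

    channel = sum_bands [ c * shared_driver_band + (1 - c) * private_noise_band ]
              + noise_sd * broadband_white

where the shared driver and the private components are white noise passed
through the same FIR band-pass filters used downstream, and c is the
group's coupling for that band.  c = 1 makes all channels share one phase
(PSI -> 1); c = 0 makes them independent (PSI near the small-sample floor).
No physiological realism (1/f spectra, artifacts, volume conduction) is
attempted — the generator exists to give downstream stages a testable,
reproducible substrate with known ground truth.

Randomness is split per (group, epoch) by counter-keyed seed sequences, so
changing the epoch count never reshuffles earlier epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import BAND_ORDER, BANDS, design_fir, _zero_phase_filter

__all__ = [
    "CoupledSignalSpec",
    "PlantedFeatureSpec",
    "LabeledEpochs",
    "generate_coupled_epochs",
    "generate_planted_features",
    "emulation_preset",
]

GROUPS = ("A", "B")


@dataclass(frozen=True)
class CoupledSignalSpec:
    """Design of a two-group coupled-signal experiment."""

    n_channels: int = 16
    fs: float = 1024.0
    epoch_len: float = 10.0
    n_epochs_per_group: int = 180
    band_coupling: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.40, 0.50),
            "theta": (0.40, 0.50),
            "alpha": (0.35, 0.65),
            "beta": (0.35, 0.65),
            "gamma": (0.35, 0.65),
        }
    )
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_epochs_per_group < 1:
            raise ValueError("n_epochs_per_group must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n = self.fs * self.epoch_len
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("epoch_len * fs must be a positive integer")
        top = 0.0
        for band, (ca, cb) in self.band_coupling.items():
            if band not in BANDS:
                raise ValueError(f"band_coupling has unknown band {band!r}")
            for c in (ca, cb):
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"coupling for band {band!r} must lie in [0, 1]")
            top = max(top, BANDS[band][1])
        if not self.fs > 2.0 * top:
            raise ValueError(
                f"fs = {self.fs} too low for highest band edge {top} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """Design of a planted-feature classification table."""

    n_samples: int = 360
    n_features: int = 70
    informative_idx: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_samples % 2 != 0:
            raise ValueError("n_samples must be even and >= 4 (balanced classes)")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        idx = tuple(self.informative_idx)
        if any(i < 0 or i >= self.n_features for i in idx):
            raise ValueError("informative_idx must lie in [0, n_features)")
        if len(set(idx)) != len(idx):
            raise ValueError("informative_idx must be unique")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class LabeledEpochs:
    """A set of multichannel epochs with group labels and stable ids."""

    epochs: list[np.ndarray]
    groups: list[str]
    epoch_ids: list[int]
    fs: float
    channel_names: list[str]

    def by_group(self, group: str) -> list[np.ndarray]:
        return [e for e, g in zip(self.epochs, self.groups) if g == group]


def _epoch_rng(seed: int, group_index: int, epoch_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, epoch_index))
    return np.random.default_rng(ss)


def generate_coupled_epochs(spec: CoupledSignalSpec) -> LabeledEpochs:
    """Simulate both groups' epochs under the shared-driver coupling model.

    Bit-identical for equal spec (including seed).  Group A uses the first
    coupling of each pair, group B the second.
    """
    n = spec.n_samples
    taps = {band: design_fir(spec.fs, band) for band in spec.band_coupling}
    epochs: list[np.ndarray] = []
    groups: list[str] = []
    epoch_ids: list[int] = []
    eid = 0
    for gi, group in enumerate(GROUPS):
        for ei in range(spec.n_epochs_per_group):
            rng = _epoch_rng(spec.seed, gi, ei)
            x = np.zeros((spec.n_channels, n))
            for band in BAND_ORDER:
                if band not in spec.band_coupling:
                    continue
                c = spec.band_coupling[band][gi]
                shared = _zero_phase_filter(rng.standard_normal(n), taps[band])[0]
                private = _zero_phase_filter(
                    rng.standard_normal((spec.n_channels, n)), taps[band]
                )
                x += c * shared[np.newaxis, :] + (1.0 - c) * private
            if spec.noise_sd > 0:
                x += spec.noise_sd * rng.standard_normal((spec.n_channels, n))
            epochs.append(x)
            groups.append(group)
            epoch_ids.append(eid)
            eid += 1
    names = [f"ch{i}" for i in range(spec.n_channels)]
    return LabeledEpochs(epochs, groups, epoch_ids, spec.fs, names)


def generate_planted_features(spec: PlantedFeatureSpec):
    """Planted-feature table: informative columns carry a between-class mean
    shift of ``effect_size`` standard deviations; the rest are pure noise.

    Returns an :class:`~psiselect.objectives.Dataset` with balanced 0/1
    labels (first half class 0, second half class 1).
    """
    from .objectives import Dataset  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(99,)))
    n, p = spec.n_samples, spec.n_features
    x = rng.standard_normal((n, p))
    labels = np.repeat([0, 1], n // 2)
    for idx in spec.informative_idx:
        x[labels == 1, idx] += spec.effect_size
    names = [f"f{i}" for i in range(p)]
    return Dataset(x, labels, names)


def emulation_preset(seed: int = 0, n_epochs_per_group: int = 180) -> CoupledSignalSpec:
    """The default study-design preset: 16 channels at 1024 Hz, 10-s epochs,
    180 epochs per group, group A (patients) more weakly coupled."""
    return CoupledSignalSpec(seed=seed, n_epochs_per_group=n_epochs_per_group)
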