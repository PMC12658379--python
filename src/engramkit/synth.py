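"""Synthetic data generators with known ground truth.

Three generators emulate the three input classes of the analysis chain:

* :func:`gen_trial_log` — manually-scored exploration bouts of a
  recognition-memory trial (novel vs. familiar object);
* :func:`gen_slice_population` — per-slice cell-count tables for
  activity-tagging experiments (DAPI / c-Fos / mCherry / double-positive);
* :func:`gen_spine_table` — per-spine morphometric feature tables like
  those exported from 3-D filament reconstructions.

Every generator takes a frozen config carrying a single integer seed; all
randomness flows through one :class:`numpy.random.Generator` derived from
it, so a fixed seed yields bit-identical tables.  Ground-truth labels and
parameters are always emitted alongside the observables so downstream
recovery tests need no re-derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

SPINE_CLASSES = ("thin", "long_thin", "mushroom", "stubby", "filopodia")


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGenConfig:
    """Generative parameters for one exploration trial.

    ``preference_novel`` is the Bernoulli probability that a bout targets
    the novel object; bout durations are log-normal with arithmetic mean
    ``bout_duration_mean`` seconds and log-scale sigma
    ``bout_duration_shape``.  Bouts are placed without overlap inside
    ``[0, trial_length]``.
    """

    preference_novel: float = 0.5
    n_bouts: int = 20
    bout_duration_mean: float = 2.0
    bout_duration_shape: float = 0.6
    trial_length: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preference_novel <= 1.0:
            raise ConfigError(f"preference_novel must be in [0, 1], got {self.preference_novel}")
        if self.n_bouts < 1:
            raise ConfigError("n_bouts must be a positive integer")
        if self.bout_duration_mean <= 0 or self.bout_duration_shape <= 0:
            raise ConfigError("bout duration mean and shape must be > 0")
        if self.trial_length <= 0:
            raise ConfigError("trial_length must be > 0")


def gen_trial_log(cfg: BehaviorGenConfig, animal_id: str = "sim", trial_id: str = "trial0"):
    """Simulate one trial's exploration log.

    Object choice is i.i.d. Bernoulli(``preference_novel``); durations are
    i.i.d. log-normal; bout onsets are placed by distributing the free time
    (trial length minus total bout time) over the inter-bout gaps with
    ordered uniform spacings, so bouts never overlap.  If the sampled
    durations exceed the trial length they are rescaled to fit, with a
    warning.
    """
    from .behavior import TrialLog  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    novel = rng.random(cfg.n_bouts) < cfg.preference_novel
    sigma = cfg.bout_duration_shape
    mu = np.log(cfg.bout_duration_mean) - sigma**2 / 2.0
    durations = rng.lognormal(mean=mu, sigma=sigma, size=cfg.n_bouts)

    total = durations.sum()
    if total >= cfg.trial_length:
        warnings.warn(
            f"sampled bout time {total:.1f}s exceeds trial length "
            f"{cfg.trial_length}s; rescaling durations to fit",
            stacklevel=2,
        )
        durations *= 0.95 * cfg.trial_length / total
        total = durations.sum()

    free = cfg.trial_length - total
    gaps = rng.random(cfg.n_bouts + 1)
    gaps = free * gaps / gaps.sum()
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    stops = starts + durations

    bouts = pd.DataFrame(
        {
            "bout_index": np.arange(cfg.n_bouts),
            "object_label": np.where(novel, "novel", "familiar"),
            "t_start_s": starts,
            "t_stop_s": stops,
        }
    )
    return TrialLog(animal_id=animal_id, trial_id=trial_id, bouts=bouts)


# --------------------------------------------------------------------------
# ensemble counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleGenConfig:
    """Generative twin of the slice-counting sampling frame.

    Each slice holds ``cells_per_slice`` DAPI+ cells in ``roi_area_mm2``.
    A cell is tagged (mCherry+) with probability ``tag_fraction``; tagged
    cells are c-Fos+ with probability ``p_react_tagged`` and untagged cells
    with ``p_active_untagged``.  The implied ground-truth overlap-over-chance
    is exposed as :attr:`expected_enrichment`.

    Optional intensity fields switch on per-c-Fos+-cell fluorescence
    simulation: baseline Normal(``intensity_mean``, ``intensity_sd``) with
    tagged cells shifted by ``intensity_tagged_shift``.
    """

    n_slices: int = 5
    cells_per_slice: int = 2000
    roi_area_mm2: float = 1.0
    tag_fraction: float = 0.05
    p_react_tagged: float = 0.42
    p_active_untagged: float = 0.08275
    seed: int = 0
    region: str = "LEC"
    intensity_mean: float | None = None
    intensity_sd: float = 0.5
    intensity_tagged_shift: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tag_fraction", "p_react_tagged", "p_active_untagged"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_slices < 1 or self.cells_per_slice < 1:
            raise ConfigError("n_slices and cells_per_slice must be positive")
        if self.roi_area_mm2 <= 0:
            raise ConfigError("roi_area_mm2 must be > 0")

    @property
    def p_cfos(self) -> float:
        """Marginal probability that a cell is c-Fos+."""
        return (
            self.tag_fraction * self.p_react_tagged
            + (1.0 - self.tag_fraction) * self.p_active_untagged
        )

    @property
    def expected_enrichment(self) -> float:
        """Ground-truth overlap/chance implied by the config.

        With independent per-cell labels the population value is
        P(cFos | tagged) / P(cFos), finite whenever the marginal c-Fos
        probability is positive.
        """
        denom = self.p_cfos
        if denom == 0.0:
            return float("nan")
        return self.p_react_tagged / denom


def gen_slice_population(
    cfg: EnsembleGenConfig, animal_id: str = "sim"
) -> pd.DataFrame:
    """Simulate slice-level count tables for one animal.

    Returns a DataFrame with one row per slice and columns
    ``animal_id, slice_id, region, area_mm2, n_dapi, n_cfos, n_mcherry,
    n_overlap``.  Counts satisfy ``n_overlap <= min(n_cfos, n_mcherry)
    <= n_dapi`` by construction.  When intensity simulation is enabled the
    frame carries a companion long-format table in ``.attrs['intensities']``
    (columns ``animal_id, slice_id, cell_id, mcherry_flag, mean_intensity``).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    intensity_rows = []
    for s in range(cfg.n_slices):
        n = cfg.cells_per_slice
        n_mch = int(rng.binomial(n, cfg.tag_fraction))
        n_overlap = int(rng.binomial(n_mch, cfg.p_react_tagged))
        n_cfos_untag = int(rng.binomial(n - n_mch, cfg.p_active_untagged))
        n_cfos = n_overlap + n_cfos_untag
        rows.append(
            {
                "animal_id": animal_id,
                "slice_id": f"{animal_id}_s{s}",
                "region": cfg.region,
                "area_mm2": cfg.roi_area_mm2,
                "n_dapi": n,
                "n_cfos": n_cfos,
                "n_mcherry": n_mch,
                "n_overlap": n_overlap,
            }
        )
        if cfg.intensity_mean is not None:
            flags = np.concatenate(
                [np.ones(n_overlap, dtype=bool), np.zeros(n_cfos_untag, dtype=bool)]
            )
            vals = rng.normal(cfg.intensity_mean, cfg.intensity_sd, size=n_cfos)
            vals = vals + cfg.intensity_tagged_shift * flags
            for c, (fl, v) in enumerate(zip(flags, vals)):
                intensity_rows.append(
                    {
                        "animal_id": animal_id,
                        "slice_id": f"{animal_id}_s{s}",
                        "cell_id": c,
                        "mcherry_flag": bool(fl),
                        "mean_intensity": float(v),
                    }
                )
    out = pd.DataFrame(rows)
    if cfg.intensity_mean is not None:
        out.attrs["intensities"] = pd.DataFrame(intensity_rows)
    return out


# --------------------------------------------------------------------------
# spines
# --------------------------------------------------------------------------

#: Per-class truncated-normal parameters (mean, sd, low, high) in µm for
#: spine length and head max diameter.  Each distribution sits well inside
#: its class's decision region so the threshold classifier recovers the
#: generating class with probability >= 0.95.  Head diameters of the
#: small-headed classes are kept above the 0.4 µm reconstruction minimum
#: so refinement does not remove genuine spines.
DEFAULT_CLASS_PARAMS: Mapping[str, Mapping[str, tuple[float, float, float, float]]] = {
    "thin": {"length": (0.75, 0.08, 0.50, 0.98), "head": (0.46, 0.025, 0.41, 0.54)},
    "long_thin": {"length": (1.50, 0.15, 1.10, 1.90), "head": (0.48, 0.030, 0.41, 0.57)},
    "mushroom": {"length": (1.00, 0.20, 0.50, 1.60), "head": (0.85, 0.080, 0.65, 1.10)},
    "stubby": {"length": (0.33, 0.04, 0.22, 0.43), "head": (0.50, 0.030, 0.44, 0.58)},
    "filopodia": {"length": (2.80, 0.30, 2.15, 3.80), "head": (0.45, 0.025, 0.41, 0.52)},
}


@dataclass(frozen=True)
class SpineGenConfig:
    """Mixture-of-classes generator for spine morphometry tables.

    ``class_mixture`` gives the five class weights in the order
    ``(thin, long_thin, mushroom, stubby, filopodia)`` and must sum to 1.
    ``neckless_fraction`` of the records have their neck diameters marked
    absent (NaN), emulating reconstruction artifacts that the refinement
    step must remove.  Spines are distributed over ``n_segments`` dendritic
    segments of ``segment_length_um`` each (default: one segment per ~25
    spines, a realistic density for 20 µm of second-order apical dendrite).
    """

    n_spines: int = 1000
    class_mixture: Sequence[float] = (0.27, 0.33, 0.21, 0.03, 0.16)
    neckless_fraction: float = 0.0
    seed: int = 0
    n_segments: int | None = None
    segment_length_um: float = 20.0
    class_params: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: DEFAULT_CLASS_PARAMS
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.class_mixture, dtype=float)
        if w.shape != (5,) or (w < 0).any():
            raise ConfigError("class_mixture must be 5 non-negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"class_mixture must sum to 1, got {w.sum()!r}")
        if not 0.0 <= self.neckless_fraction <= 1.0:
            raise ConfigError("neckless_fraction must be in [0, 1]")
        if self.n_spines < 1:
            raise ConfigError("n_spines must be positive")


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size: int) -> np.ndarray:
    """Truncated normal via rejection; parameters keep acceptance high."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def gen_spine_table(cfg: SpineGenConfig, neuron_id: str = "sim_n0") -> pd.DataFrame:
    """Sample a spine morphometry table from the class mixture.

    Returns one row per spine with the measured features (µm), segment
    assignment, and the generating class in a ``true_class`` sidecar
    column.  ``neckless_fraction`` of the rows have NaN neck diameters.
    """
    rng = np.random.default_rng(cfg.seed)
    w = np.asarray(cfg.class_mixture, dtype=float)
    labels = rng.choice(len(SPINE_CLASSES), size=cfg.n_spines, p=w / w.sum())

    length = np.empty(cfg.n_spines)
    head_max = np.empty(cfg.n_spines)
    for k, cls in enumerate(SPINE_CLASSES):
        m = labels == k
        if not m.any():
            continue
        p = cfg.class_params[cls]
        length[m] = _trunc_normal(rng, *p["length"], int(m.sum()))
        head_max[m] = _trunc_normal(rng, *p["head"], int(m.sum()))

    n = cfg.n_spines
    head_mean = head_max * rng.uniform(0.75, 0.92, n)
    head_length = length * rng.uniform(0.25, 0.40, n)
    neck_mean = head_max * rng.uniform(0.50, 0.75, n)
    neck_min = neck_mean * rng.uniform(0.70, 0.95, n)
    neck_length = np.maximum(length - head_length, 0.05) * rng.uniform(0.85, 1.0, n)
    attachment = neck_mean * rng.uniform(0.90, 1.15, n)
    straightness = rng.uniform(0.80, 1.0, n)

    neckless = rng.random(n) < cfg.neckless_fraction
    neck_min = np.where(neckless, np.nan, neck_min)
    neck_mean = np.where(neckless, np.nan, neck_mean)

    n_segments = cfg.n_segments or max(1, round(n / 25))
    segment = rng.integers(0, n_segments, size=n)

    df = pd.DataFrame(
        {
            "spine_id": [f"{neuron_id}_sp{i}" for i in range(n)],
            "neuron_id": neuron_id,
            "segment_id": [f"{neuron_id}_seg{s}" for s in segment],
            "length": length,
            "head_max_diameter": head_max,
            "head_mean_diameter": head_mean,
            "head_length": head_length,
            "neck_min_diameter": neck_min,
            "neck_mean_diameter": neck_mean,
            "neck_length": neck_length,
            "attachment_diameter": attachment,
            "straightness": straightness,
            "true_class": [SPINE_CLASSES[k] for k in labels],
        }
    )
    df.attrs["segment_length_um"] = cfg.segment_length_um
    return df


def child_seed(seed: int, index: int) -> int:
    """Deterministic substream seed derived from a single global seed."""
    return int(np.random.SeedSequence(seed).spawn(index + 1)[index].generate_state(1)[0] % (2**31))
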