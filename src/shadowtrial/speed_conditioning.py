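"""Response probability conditioned on pre-stimulus speed, and the
speed-matched virtual-fly null model.

The "outer model" is an empirical :class:`SpeedResponseCurve`: trials pooled
across groups are binned by their pre-stimulus speed ``v_pre`` and the
per-bin frequencies of the four response labels estimated.  The "inner
model" simulates a cohort of virtual flies for one genotype: each virtual
fly draws a speed (with replacement) from that genotype's empirical ``v_pre``
distribution and then a response label from the pooled curve at that speed.
Comparing virtual and observed label counts with a chi-square test asks
whether baseline walking speed alone explains a genotype's response mix: a
significant result points at behavioral differences beyond speed.

By default the comparison is the 2 x k contingency chi-square between the
two count vectors, which accounts for the Monte-Carlo error of the finite
virtual cohort and is therefore calibrated for any cohort size.  A classical
goodness-of-fit variant (virtual proportions treated as exact) is available
as ``method="gof"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import LABELS, V_ZERO
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_N_VIRTUAL = 3000


def default_bin_edges(v_zero: float = V_ZERO, top: float = 20.0,
                      step: float = 2.0) -> np.ndarray:
    """Speed bin edges: a dedicated stationary bin [0, v_zero), then 2 mm/s
    bins up to ``top``, then an overflow bin."""
    return np.concatenate([[0.0, v_zero], np.arange(step, top + step / 2, step),
                           [np.inf]])


@dataclass
class SpeedResponseCurve:
    """Per-speed-bin probability vectors over the four response labels.

    ``probs`` has one row per bin in the order of :data:`LABELS`; rows of
    unpopulated bins are NaN and flagged by ``counts == 0`` rather than
    imputed.
    """

    bin_edges: np.ndarray
    probs: np.ndarray
    counts: np.ndarray = field(default=None)  # trials per bin; zeros if configured

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        n_bins = len(self.bin_edges) - 1
        if self.probs.shape != (n_bins, len(LABELS)):
            raise ParameterError(
                f"probs must have shape ({n_bins}, {len(LABELS)})"
            )
        if self.counts is None:
            self.counts = np.zeros(n_bins, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        pop = self.populated
        sums = self.probs[pop].sum(axis=1)
        if pop.any() and not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError("populated bins must have probabilities summing to 1")
        # a fly that is not moving cannot stop or slow down
        if pop[0] and (self.probs[0, 0] != 0 or self.probs[0, 1] != 0):
            raise ParameterError(
                "stop/slow probability must be 0 in the stationary speed bin"
            )

    @property
    def populated(self) -> np.ndarray:
        """Bins with data (or, for configured curves, finite probabilities)."""
        finite = np.isfinite(self.probs).all(axis=1)
        if self.counts.sum() > 0:
            return (self.counts > 0) & finite
        return finite

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_index(self, speeds: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges, np.asarray(speeds, dtype=float),
                              side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def probs_for_speed(self, speeds: np.ndarray) -> np.ndarray:
        """Label probabilities at each speed; out-of-support speeds use the
        nearest populated bin (logged)."""
        idx = self.bin_index(speeds)
        pop = np.flatnonzero(self.populated)
        if len(pop) == 0:
            raise DataError("curve has no populated bins")
        bad = ~self.populated[idx]
        if bad.any():
            logger.info("%d draw(s) outside the curve support; using nearest "
                        "populated bin", int(bad.sum()))
            nearest = pop[np.argmin(np.abs(idx[bad][:, None] - pop[None, :]), axis=1)]
            idx = idx.copy()
            idx[bad] = nearest
        return self.probs[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=[f"p_{lab}" for lab in LABELS])
        df.insert(0, "bin_lo", self.bin_edges[:-1])
        df.insert(1, "bin_hi", self.bin_edges[1:])
        df.insert(2, "n", self.counts)
        return df


@dataclass
class VirtualCohortResult:
    """Outcome of the virtual-fly null test for one genotype."""

    genotype: str
    n_virtual: int
    predicted_counts: dict
    observed_counts: dict
    statistic: float
    df: int
    pvalue: float
    seed: int | None = None
    method: str = "contingency"


def build_curve(
    trials: pd.DataFrame, bin_edges: np.ndarray | None = None
) -> SpeedResponseCurve:
    """Empirical speed-conditioned response curve from classified trials.

    ``trials`` needs ``v_pre`` and ``label`` columns (a ``valid`` column, if
    present, filters unscored trials).  Probabilities are per-bin label
    frequencies pooled over all supplied trials.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    scored = trials
    if "valid" in trials:
        scored = trials[trials["valid"].astype(bool)]
    scored = scored[scored["label"].isin(LABELS)]
    if scored.empty:
        raise DataError("no scored trials to build a curve from")
    n_bins = len(bin_edges) - 1
    idx = np.clip(
        np.searchsorted(bin_edges, scored["v_pre"].to_numpy(), side="right") - 1,
        0, n_bins - 1,
    )
    lab_idx = scored["label"].map({lab: k for k, lab in enumerate(LABELS)}).to_numpy()
    counts2d = np.zeros((n_bins, len(LABELS)))
    np.add.at(counts2d, (idx, lab_idx), 1.0)
    totals = counts2d.sum(axis=1)
    probs = np.full_like(counts2d, np.nan)
    nz = totals > 0
    probs[nz] = counts2d[nz] / totals[nz, None]
    if nz.sum() < len(nz):
        logger.info("%d empty speed bin(s) flagged", int((~nz).sum()))
    return SpeedResponseCurve(bin_edges, probs, totals.astype(int))


def simulate_virtual_cohort(
    speeds: np.ndarray,
    curve: SpeedResponseCurve,
    n_virtual: int = DEFAULT_N_VIRTUAL,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Inner model: label counts of ``n_virtual`` virtual flies.

    Each virtual fly resamples a pre-stimulus speed from the empirical
    ``speeds`` (with replacement) and draws a label from the curve at that
    speed.  Returns the length-4 count vector in :data:`LABELS` order.
    """
    speeds = np.asarray(speeds, dtype=float)
    if len(speeds) == 0:
        raise DataError("empty speed sample")
    if n_virtual < 1:
        raise ParameterError("n_virtual must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    drawn = rng.choice(speeds, size=n_virtual, replace=True)
    p = curve.probs_for_speed(drawn)
    r = rng.random(n_virtual)
    lab = (r[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    return np.bincount(lab, minlength=len(LABELS))


def test_prediction(
    observed: np.ndarray | dict,
    predicted: np.ndarray | dict,
    method: str = "contingency",
) -> tuple[float, int, float]:
    """Chi-square comparison of observed vs virtual-fly label counts.

    ``method="contingency"`` (default) treats both vectors as multinomial
    samples (2 x k Pearson chi-square, no continuity correction).
    ``method="gof"`` scales the virtual proportions to the observed total and
    computes the classical goodness-of-fit statistic with df = k - 1.
    Label categories with no counts in either vector are merged out (logged).
    Returns (statistic, df, pvalue).
    """
    obs = np.asarray([observed[k] for k in LABELS] if isinstance(observed, dict)
                     else observed, dtype=float)
    pred = np.asarray([predicted[k] for k in LABELS] if isinstance(predicted, dict)
                      else predicted, dtype=float)
    if obs.sum() == 0:
        raise DataError("observed counts are all zero")
    if pred.sum() == 0:
        raise DataError("predicted counts are all zero")
    keep = (obs + pred) > 0
    if keep.sum() < len(obs):
        logger.info("merging %d empty label categories", int((~keep).sum()))
    obs, pred = obs[keep], pred[keep]
    if keep.sum() < 2:
        raise DataError("need at least two non-empty categories")
    if method == "contingency":
        stat, p, df, _ = stats.chi2_contingency(np.vstack([obs, pred]),
                                                correction=False)
        return float(stat), int(df), float(p)
    if method == "gof":
        expected = pred / pred.sum() * obs.sum()
        stat = float(((obs - expected) ** 2 / expected).sum())
        df = len(obs) - 1
        return stat, df, float(stats.chi2.sf(stat, df))
    raise ParameterError(f"unknown method {method!r}")


def run_virtual_fly_test(
    trials: pd.DataFrame,
    curve: SpeedResponseCurve,
    genotype: str,
    n_virtual: int = DEFAULT_N_VIRTUAL,
    seed: int | None = None,
    method: str = "contingency",
) -> VirtualCohortResult:
    """Full speed-matched null test for one genotype's classified trials."""
    scored = trials[trials["valid"].astype(bool)] if "valid" in trials else trials
    scored = scored[scored["label"].isin(LABELS)]
    if scored.empty:
        raise DataError(f"no scored trials for genotype {genotype!r}")
    observed = np.array([(scored["label"] == lab).sum() for lab in LABELS],
                        dtype=float)
    predicted = simulate_virtual_cohort(scored["v_pre"].to_numpy(), curve,
                                        n_virtual, seed)
    stat, df, p = test_prediction(observed, predicted, method=method)
    return VirtualCohortResult(
        genotype=genotype, n_virtual=n_virtual,
        predicted_counts=dict(zip(LABELS, predicted.astype(int).tolist())),
        observed_counts=dict(zip(LABELS, observed.astype(int).tolist())),
        statistic=stat, df=df, pvalue=p, seed=seed, method=method,
    )
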