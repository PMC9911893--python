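"""Ks-distribution peak fitting for nested WGDs.

The paralog Ks distribution of a twice-duplicated genome shows one peak
per WGD.  Following the standard WGDI-style procedure, the sample is
restricted to a Ks window, split at the fixed inter-peak trough, and a
Gaussian is fitted to each subset's own histogram density by least
squares, with the peak initialised at the subset median ("mode=median")
and the scale at half the interquartile range.  Fitting a plain Gaussian
to a trough-clipped subset is the procedure being reproduced; its
truncation bias is accepted, not corrected.

``KsMixtureModel`` / ``KsMixtureResults`` expose this as a model object in
the statsmodels idiom; the module-level functions are the underlying
operations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class MixtureError(ValueError):
    pass


DEFAULT_RANGE = (0.05, 1.5)
DEFAULT_TROUGH = 0.6
DEFAULT_BINS = 200
MIN_COMPONENT_SIZE = 50


def ks_histogram(
    values: Sequence[float],
    n_bins: int = DEFAULT_BINS,
    range: tuple[float, float] = DEFAULT_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised Ks histogram: bin edges and densities integrating to 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise MixtureError("cannot build a histogram from an empty sample")
    lo, hi = range
    if np.any((values < lo) | (values > hi)):
        raise MixtureError(f"values outside the histogram range ({lo}, {hi})")
    densities, edges = np.histogram(values, bins=n_bins, range=(lo, hi), density=True)
    return edges, densities


def split_at_trough(
    values: Sequence[float], trough: float = DEFAULT_TROUGH
) -> tuple[np.ndarray, np.ndarray]:
    """Partition values at the inter-peak trough: young < trough <= old."""
    values = np.asarray(values, dtype=float)
    return values[values < trough], values[values >= trough]


def _gaussian(x: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_component(
    subset: Sequence[float],
    mode: str = "median",
    n_bins: int = DEFAULT_BINS,
    total_n: int | None = None,
) -> tuple[float, float, float]:
    """Least-squares Gaussian fit to one trough-side subset.

    The subset's own ``n_bins``-bin density (over its data range) is fitted
    with an amplitude-free Gaussian; the peak is initialised at the subset
    median and the scale at half the interquartile range.  Returns
    (peak, sd, weight) with weight = len(subset) / total_n.
    """
    if mode != "median":
        raise MixtureError(f"unknown initialization mode {mode!r}")
    subset = np.asarray(subset, dtype=float)
    if subset.size < MIN_COMPONENT_SIZE:
        raise MixtureError(
            f"subset of {subset.size} values is too small to fit "
            f"(need >= {MIN_COMPONENT_SIZE}); lower n_bins or pool more data"
        )
    lo, hi = float(subset.min()), float(subset.max())
    if hi <= lo:
        raise MixtureError("subset is degenerate (all values equal)")
    densities, edges = np.histogram(subset, bins=n_bins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    median = float(np.median(subset))
    q1, q3 = np.percentile(subset, [25, 75])
    sd0 = max((q3 - q1) / 2.0, (hi - lo) / n_bins)
    p0 = (float(densities.max()), median, sd0)
    bounds = ([0.0, lo, 1e-9], [np.inf, hi, hi - lo])
    params, _ = curve_fit(
        _gaussian, centers, densities, p0=p0, bounds=bounds, maxfev=20000
    )
    _amp, peak, sd = params
    total = total_n if total_n is not None else subset.size
    return float(peak), float(abs(sd)), subset.size / total


@dataclass
class MixtureFit:
    """Per-component peak/scale/weight plus the trough used to split."""

    components: list[tuple[float, float, float]]  # (peak, sd, weight)
    trough: float
    n_bins: int
    range: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c[0])

    @property
    def peaks(self) -> list[float]:
        return [c[0] for c in self.components]

    def to_dict(self) -> dict:
        return {
            "components": [
                {"peak": p, "sd": s, "weight": w} for p, s, w in self.components
            ],
            "trough": self.trough,
            "n_bins": self.n_bins,
            "range": list(self.range),
            "n": self.n,
        }


def fit_wgd_peaks(
    values: Sequence[float],
    trough: float = DEFAULT_TROUGH,
    n_bins: int = DEFAULT_BINS,
    range: tuple[float, float] = DEFAULT_RANGE,
    on_small: str = "raise",
) -> MixtureFit:
    """Split the Ks sample at the trough and fit one Gaussian per side.

    ``on_small`` controls the degenerate single-WGD case: "raise" errors
    when a subset is too small, "skip" returns the fittable components
    only (possibly none).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = range
    if np.any((values <= lo) | (values >= hi)):
        raise MixtureError(f"values must be pre-filtered to the open interval ({lo}, {hi})")
    young, old = split_at_trough(values, trough)
    components = []
    for subset in (young, old):
        try:
            components.append(fit_component(subset, n_bins=n_bins, total_n=values.size))
        except MixtureError:
            if on_small == "raise":
                raise
    return MixtureFit(components, trough, n_bins, (lo, hi), int(values.size))


class KsMixtureModel:
    """Trough-split Gaussian peak model for a paralog Ks sample.

    Parameters
    ----------
    values : array-like
        Ks estimates already filtered to the open interval ``range``.
    trough : float
        Fixed split point between the young and old WGD components.
    n_bins : int
        Histogram resolution used both for splitting diagnostics and for
        the least-squares fit.
    range : (float, float)
        The analysis window.
    """

    def __init__(
        self,
        values: Sequence[float],
        trough: float = DEFAULT_TROUGH,
        n_bins: int = DEFAULT_BINS,
        range: tuple[float, float] = DEFAULT_RANGE,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        self.trough = trough
        self.n_bins = n_bins
        self.range = range

    def fit(self, on_small: str = "raise") -> "KsMixtureResults":
        mixture = fit_wgd_peaks(
            self.values, self.trough, self.n_bins, self.range, on_small=on_small
        )
        return KsMixtureResults(self, mixture)


class KsMixtureResults:
    """Fitted WGD peak locations, scales and weights."""

    def __init__(self, model: KsMixtureModel, mixture: MixtureFit) -> None:
        self.model = model
        self.mixture = mixture

    @property
    def components(self) -> list[tuple[float, float, float]]:
        return self.mixture.components

    @property
    def peaks(self) -> list[float]:
        return self.mixture.peaks

    def summary(self) -> str:
        lines = [
            "Ks mixture fit",
            f"  n = {self.mixture.n}, trough = {self.mixture.trough}, "
            f"bins = {self.mixture.n_bins}, range = {self.mixture.range}",
            f"  {'component':<10}{'peak':>8}{'sd':>8}{'weight':>8}",
        ]
        names = ["young", "old", *[f"c{i}" for i in range(2, 9)]]
        for name, (peak, sd, weight) in zip(names, self.mixture.components):
            lines.append(f"  {name:<10}{peak:>8.3f}{sd:>8.3f}{weight:>8.3f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(self.mixture.to_dict(), indent=2)

    def density_table(self) -> pd.DataFrame:
        """Per-subset binned densities suitable for external plotting."""
        frames = []
        names = ["young", "old"]
        young, old = split_at_trough(self.model.values, self.mixture.trough)
        for name, subset in zip(names, (young, old)):
            if subset.size == 0:
                continue
            densities, edges = np.histogram(
                subset,
                bins=self.mixture.n_bins,
                range=(float(subset.min()), float(subset.max())),
                density=True,
            )
            centers = 0.5 * (edges[:-1] + edges[1:])
            frames.append(
                pd.DataFrame(
                    {"component": name, "ks": centers, "density": densities}
                )
            )
        if not frames:
            return pd.DataFrame(columns=["component", "ks", "density"])
        return pd.concat(frames, ignore_index=True)
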