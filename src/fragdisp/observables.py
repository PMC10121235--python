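"""Summary statistics and exports: genotype totals, mean dispersal ability,
uniformity statistic, and normalized density frames."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SummarySeries",
    "totals",
    "mean_dispersal",
    "sigma_over_mean",
    "normalized_frames",
    "snapshots_to_dataset",
]


def totals(fields: np.ndarray, dx: float) -> tuple[np.ndarray, float]:
    """Per-genotype totals ``P_k = dx**2 * sum_nodes Psi_k`` and their sum.

    Plain Riemann sum with weight ``dx**2``, which is exact in spirit on a
    periodic tile (every node carries equal area).
    """
    fields = np.asarray(fields, dtype=float)
    Pk = fields.sum(axis=tuple(range(1, fields.ndim))) * dx**2
    return Pk, float(Pk.sum())


def mean_dispersal(Pk: np.ndarray, a0: float = 1.0) -> float | None:
    """Population-weighted mean dispersal ability
    ``abar = sum_k P_k * a0 * k / sum_k P_k`` with ``k = 1..n``.

    Returns ``None`` (a missing value, not zero) when the population is empty.
    """
    Pk = np.asarray(Pk, dtype=float)
    P = Pk.sum()
    if P <= 0:
        return None
    ks = a0 * np.arange(1, Pk.size + 1)
    return float((Pk * ks).sum() / P)


def sigma_over_mean(field: np.ndarray) -> float:
    """Uniformity statistic for one genotype field: the (unweighted) standard
    deviation of node values divided by their mean.  Infinite when the mean
    is zero, which simply means "nowhere near uniform-and-positive"."""
    m = float(field.mean())
    if m <= 0:
        return np.inf
    return float(field.std() / m)


@dataclass
class SummarySeries:
    """Time series of scalar summaries sampled at accepted integrator steps.

    Attributes
    ----------
    t : (T,) ascending times
    Pk : (T, n) per-genotype totals
    sigma_ratio : (T,) uniformity statistic of the slowest genotype's field
    a0 : dispersal-ability unit used when reporting ``a_bar``
    """

    t: np.ndarray
    Pk: np.ndarray
    sigma_ratio: np.ndarray
    a0: float = 1.0

    @property
    def n(self) -> int:
        return self.Pk.shape[1]

    @property
    def P(self) -> np.ndarray:
        return self.Pk.sum(axis=1)

    @property
    def a_bar(self) -> np.ndarray:
        """Mean dispersal ability per sample; NaN where the population is empty."""
        ks = self.a0 * np.arange(1, self.n + 1)
        P = self.P
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = (self.Pk @ ks) / P
        ab = np.asarray(ab)
        ab[P <= 0] = np.nan
        return ab

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for k in range(self.n):
            cols[f"P{k + 1}"] = self.Pk[:, k]
        cols["P"] = self.P
        cols["a_bar"] = self.a_bar
        cols["sigma_over_mean"] = self.sigma_ratio
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        # 17 significant digits: doubles survive the round trip bit-for-bit
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, a0: float = 1.0) -> "SummarySeries":
        df = pd.read_csv(path, float_precision="round_trip")
        pk_cols = [c for c in df.columns if c.startswith("P") and c[1:].isdigit()]
        pk_cols.sort(key=lambda c: int(c[1:]))
        return cls(
            t=df["t"].to_numpy(),
            # C order: keeps derived statistics bit-identical to in-memory ones
            Pk=np.ascontiguousarray(df[pk_cols].to_numpy()),
            sigma_ratio=df["sigma_over_mean"].to_numpy(),
            a0=a0,
        )

    def final_a_bar(self) -> float | None:
        """Mean dispersal ability at the last sample; None if extinct."""
        ab = self.a_bar
        return None if np.isnan(ab[-1]) else float(ab[-1])

    def a_bar_at(self, t: float) -> float | None:
        """Mean dispersal ability at the sample closest to time ``t``."""
        idx = int(np.argmin(np.abs(self.t - t)))
        ab = self.a_bar[idx]
        return None if np.isnan(ab) else float(ab)


def normalized_frames(stacks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative densities ``Psi_k(x, y; t) / max_{x,y,k} Psi(x, y; t)``.

    Parameters
    ----------
    stacks : (T, n, ny, nx) array of genotype stacks over time.

    Returns
    -------
    frames : same shape, each time slice divided by its global maximum,
        values in [0, 1].
    blank : (T,) boolean flags marking all-zero frames (left as zeros).
    """
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim != 4:
        raise ValueError("expected a (time, genotype, y, x) array")
    frames = np.empty_like(stacks)
    blank = np.zeros(stacks.shape[0], dtype=bool)
    for ti in range(stacks.shape[0]):
        m = stacks[ti].max()
        if m <= 0:
            frames[ti] = 0.0
            blank[ti] = True
        else:
            frames[ti] = stacks[ti] / m
    return frames, blank


def snapshots_to_dataset(times, stacks, grid):
    """Pack field snapshots into an :class:`xarray.Dataset` with dimensions
    (time, genotype, y, x); write with ``ds.to_netcdf(path, engine="scipy")``."""
    import xarray as xr

    stacks = np.asarray(stacks, dtype=float)
    n = stacks.shape[1]
    return xr.Dataset(
        {"Psi": (("time", "genotype", "y", "x"), stacks)},
        coords={
            "time": np.asarray(times, dtype=float),
            "genotype": np.arange(1, n + 1),
            "y": grid.y,
            "x": grid.x,
        },
    )
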