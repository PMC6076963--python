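"""Window location × size grid scan with FDR control.

For every cell of a grid of window specifications (start offset in minutes
relative to each EMA prompt × window duration), the scan computes the chosen
local activity statistic for every prompt, person-centers it, fits the
univariate random-intercept multilevel model

    affect_tj = γ00 + γ10 (X_tj − X̄_j) + ζ0j + ε_tj,

and records γ̂10 with its Wald p-value.  The p-values of all cells that could
be fitted are then jointly adjusted by the Benjamini–Hochberg step-up
procedure at level q (Storey's π0-adaptive variant available), and the result
is a trio of location × size matrices: slopes, p-values and an FDR
significance mask.

The default grid is 25 locations (−60 … +60 min, step 5) × 12 sizes
(10 … 120 min, step 10) = 300 cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmaScanError, InsufficientDataError, ValidationError
from .io import EmaObservation, EpochSeries, write_scan_matrix
from .local_stats import LocalStatConfig, WindowSpec, compute_local_stat
from .mlm import fit_scan_model

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "ScanResults",
    "WindowScan",
    "build_grid",
    "default_grid",
    "run_scan",
    "fdr_adjust",
]


@dataclass(frozen=True)
class WindowGrid:
    """All (location, size) pairs of a scan.

    ``locations`` ascend; ``sizes`` are stored descending (matrix row 0 is the
    largest window).  Display/serialization puts the smallest size on top.
    """

    locations: tuple
    sizes: tuple

    def __post_init__(self) -> None:
        if len(self.locations) == 0 or len(self.sizes) == 0:
            raise ValidationError("grid must have at least one location and one size")
        if any(s <= 0 for s in self.sizes):
            raise ValidationError("window sizes must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.locations) * len(self.sizes)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.sizes), len(self.locations))

    def cells(self):
        """Iterate (row, col, WindowSpec) over the full Cartesian grid."""
        for r, size in enumerate(self.sizes):
            for c, loc in enumerate(self.locations):
                yield r, c, WindowSpec(location=loc, size=size)

    def row_of(self, size: float) -> int:
        return self.sizes.index(size)


def _steps(lo: float, hi: float, step: float) -> tuple:
    if step <= 0:
        raise ValidationError("step must be positive")
    if lo > hi:
        raise ValidationError("min must not exceed max")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValidationError(f"step {step} does not divide the range [{lo}, {hi}]")
    return tuple(lo + i * step for i in range(int(round(n)) + 1))


def build_grid(
    loc_min: float = -60,
    loc_max: float = 60,
    loc_step: float = 5,
    size_min: float = 10,
    size_max: float = 120,
    size_step: float = 10,
) -> WindowGrid:
    """Full Cartesian grid of window locations × sizes (defaults: 25 × 12)."""
    locations = _steps(loc_min, loc_max, loc_step)
    sizes = tuple(reversed(_steps(size_min, size_max, size_step)))
    return WindowGrid(locations=locations, sizes=sizes)


def default_grid() -> WindowGrid:
    """The canonical 300-cell grid: −60..60 by 5 min × 10..120 by 10 min."""
    return build_grid()


def fdr_adjust(p_values, q: float = 0.05, method: str = "bh", pi0_lambda: float = 0.5):
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``.

    NaN entries are excluded from the number of tests m and come back False.
    ``method="storey"`` first estimates the null fraction π0 from the p-value
    histogram (Storey's estimator at λ) and runs the step-up at level q/π0.
    """
    if not (0 < q < 1):
        raise ValidationError("q must be in (0, 1)")
    if method not in ("bh", "storey"):
        raise ValidationError("method must be 'bh' or 'storey'")
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return mask
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")

    level = q
    if method == "storey":
        pi0 = min(1.0, float(np.mean(pv > pi0_lambda)) / (1.0 - pi0_lambda))
        if pi0 > 0:
            level = min(q / pi0, 1 - 1e-12)

    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    thresh = level * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    rejected = np.zeros(m, dtype=bool)
    if below.size:
        k = below[-1]
        rejected[order[: k + 1]] = True
    mask[valid] = rejected
    return mask


class ScanResults:
    """Matrices of per-cell slope estimates, p-values and FDR significance."""

    def __init__(
        self,
        grid: WindowGrid,
        slopes: np.ndarray,
        pvalues: np.ndarray,
        n_obs: np.ndarray,
        significant: np.ndarray,
        statistic: str,
        detrend_order,
        q: float,
        fdr_method: str = "bh",
        failures: list | None = None,
    ):
        self.grid = grid
        self.slopes = slopes
        self.pvalues = pvalues
        self.n_obs = n_obs
        self.significant = significant
        self.statistic = statistic
        self.detrend_order = detrend_order
        self.q = q
        self.fdr_method = fdr_method
        self.failures = failures or []

    def _frame(self, matrix) -> pd.DataFrame:
        return pd.DataFrame(
            matrix, index=list(self.grid.sizes), columns=list(self.grid.locations)
        )

    @property
    def slope_frame(self) -> pd.DataFrame:
        return self._frame(self.slopes)

    @property
    def pvalue_frame(self) -> pd.DataFrame:
        return self._frame(self.pvalues)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_tsv(self, prefix: str) -> None:
        """Write the three scan matrices (slope, p-value, significance)."""
        write_scan_matrix(self, prefix)

    def max_abs_cell(self) -> tuple[float, float]:
        """(location, size) of the largest |slope| among fitted cells."""
        a = np.abs(self.slopes)
        if np.all(np.isnan(a)):
            raise EmaScanError("no fitted cells")
        r, c = np.unravel_index(np.nanargmax(a), a.shape)
        return self.grid.locations[c], self.grid.sizes[r]

    def summary(self) -> str:
        fitted = int(np.sum(~np.isnan(self.pvalues)))
        lines = [
            f"Window scan of local {self.statistic}"
            + (f" (detrend order {self.detrend_order})" if self.detrend_order is not None else ""),
            f"Grid: {len(self.grid.locations)} locations x {len(self.grid.sizes)} sizes"
            f" = {self.grid.n_cells} cells ({fitted} fitted, {len(self.failures)} failed)",
            f"FDR ({self.fdr_method}) at q={self.q}: {self.n_significant} significant cells",
        ]
        if fitted:
            loc, size = self.max_abs_cell()
            r, c = self.grid.row_of(size), list(self.grid.locations).index(loc)
            lines.append(
                f"Largest |slope| {self.slopes[r, c]:+.4g} at location {loc:g} min,"
                f" size {size:g} min (p={self.pvalues[r, c]:.3g})"
            )
        return "\n".join(lines)

    def plot(self, ax=None, which: str = "slope", mask_nonsig: bool = True):
        """Convenience heatmap of the slope (or p-value) matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        data = self.slopes if which == "slope" else self.pvalues
        # display with smallest size on top, like the serialized matrices
        order = np.argsort(np.asarray(self.grid.sizes))
        disp = data[order, :].astype(float)
        if mask_nonsig and which == "slope":
            disp = np.where(self.significant[order, :], disp, np.nan)
        vmax = np.nanmax(np.abs(disp)) if np.any(~np.isnan(disp)) else 1.0
        im = ax.imshow(
            disp, aspect="auto", cmap="coolwarm", vmin=-vmax, vmax=vmax,
            interpolation="nearest",
        )
        ax.set_xticks(range(len(self.grid.locations)))
        ax.set_xticklabels([f"{l:g}" for l in self.grid.locations], rotation=90)
        ax.set_yticks(range(len(self.grid.sizes)))
        ax.set_yticklabels([f"{self.grid.sizes[i]:g}" for i in order])
        ax.set_xlabel("window location (min relative to prompt)")
        ax.set_ylabel("window size (min)")
        ax.figure.colorbar(im, ax=ax, label="slope" if which == "slope" else "p")
        return ax


class WindowScan:
    """Scan model object: activity + EMA data over a window grid.

    ``fit(q=...)`` runs the full scan and returns :class:`ScanResults`.
    The scan is deterministic: no randomness enters after the inputs.
    """

    def __init__(
        self,
        activity: dict[str, EpochSeries],
        ema: list[EmaObservation],
        grid: WindowGrid | None = None,
        config: LocalStatConfig | None = None,
    ):
        self.activity = activity
        self.ema = list(ema)
        self.grid = grid if grid is not None else default_grid()
        self.config = config if config is not None else LocalStatConfig()
        missing = sorted({o.subject_id for o in self.ema} - set(activity))
        if missing:
            raise ValidationError(f"EMA subjects without activity data: {missing}")
        if self.grid.n_cells == 0:
            raise ValidationError("empty window grid")

    def _cell_data(self, spec: WindowSpec) -> pd.DataFrame:
        rows = []
        for obs in self.ema:
            series = self.activity[obs.subject_id]
            v = compute_local_stat(series, obs, spec, self.config)
            rows.append(
                {"subject": obs.subject_id, "day": obs.day_index,
                 "affect": obs.affect, "x": v.value}
            )
        return pd.DataFrame(rows)

    def fit(self, q: float = 0.05, fdr_method: str = "bh", reml: bool = True) -> ScanResults:
        if not (0 < q < 1):
            raise ValidationError("q must be in (0, 1)")
        shape = self.grid.shape
        slopes = np.full(shape, np.nan)
        pvals = np.full(shape, np.nan)
        nobs = np.zeros(shape, dtype=int)
        failures = []
        for r, c, spec in self.grid.cells():
            data = self._cell_data(spec)
            try:
                res = fit_scan_model(data, reml=reml)
            except (InsufficientDataError, EmaScanError) as exc:
                failures.append((spec, str(exc)))
                logger.info("cell %s failed: %s", spec, exc)
                continue
            if not res.converged or not np.isfinite(res.slope_pvalue):
                failures.append((spec, "fit did not converge"))
                logger.info("cell %s did not converge", spec)
                continue
            slopes[r, c] = res.slope
            pvals[r, c] = res.slope_pvalue
            nobs[r, c] = res.n_obs
        sig = fdr_adjust(pvals, q=q, method=fdr_method)
        return ScanResults(
            grid=self.grid, slopes=slopes, pvalues=pvals, n_obs=nobs,
            significant=sig, statistic=self.config.statistic,
            detrend_order=self.config.detrend_order, q=q,
            fdr_method=fdr_method, failures=failures,
        )


def run_scan(
    activity: dict[str, EpochSeries],
    ema: list[EmaObservation],
    grid: WindowGrid | None = None,
    config: LocalStatConfig | None = None,
    q: float = 0.05,
    fdr_method: str = "bh",
) -> ScanResults:
    """Functional wrapper: build a :class:`WindowScan` and fit it."""
    return WindowScan(activity, ema, grid=grid, config=config).fit(
        q=q, fdr_method=fdr_method
    )
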