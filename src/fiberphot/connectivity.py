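"""State-conditioned multi-regional functional connectivity.

Inter-region coupling is quantified by Spearman rank correlation between
z-scored traces restricted to one behavioral state (stationary or movement),
per cell type; astrocyte-neuron coupling within a region by the peak of the
lagged Pearson cross-correlation.  Matrices map onto connectivity graphs whose
nodes carry stereotaxic (AP, ML) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import StateSegments
from .stats import StatResult, summarize_mean_sem, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = [
    "REGION_COORDS_MM",
    "ConnectivityMatrix",
    "CrossCorrResult",
    "ConnectivityGraph",
    "state_conditioned_series",
    "interregion_spearman",
    "astro_neuron_crosscorr",
    "build_graph",
    "state_contrast",
]

# Stereotaxic injection coordinates (AP, ML) in mm for the recorded regions.
REGION_COORDS_MM = {
    "S1": (-0.5, -1.9),
    "M1": (0.0, 1.0),
    "CA1": (-2.1, 1.55),
}


@dataclass
class ConnectivityMatrix:
    r: np.ndarray
    regions: list[str]
    cell_type: str
    state: str
    n_samples: int
    undefined: np.ndarray | None = None  # mask of entries with constant input

    def mean_offdiag(self) -> float:
        iu = np.triu_indices(len(self.regions), k=1)
        vals = self.r[iu]
        if self.undefined is not None:
            vals = vals[~self.undefined[iu]]
        return float(np.nanmean(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)


@dataclass
class CrossCorrResult:
    lags_s: np.ndarray
    r_at_lag: np.ndarray
    state: str = ""
    region: str = ""

    @property
    def peak_r(self) -> float:
        return float(np.max(self.r_at_lag))

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[int(np.argmax(self.r_at_lag))])


@dataclass
class ConnectivityGraph:
    nodes: dict[str, tuple[float, float]]
    edges: list[tuple[str, str, float]]
    state: str = ""
    cell_type: str = ""

    def edge_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.edges, columns=["source", "target", "weight"])
        df["state"] = self.state
        df["cell_type"] = self.cell_type
        return df

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, ap, ml) for k, (ap, ml) in self.nodes.items()],
            columns=["region", "ap_mm", "ml_mm"],
        )


def state_conditioned_series(
    traces: dict[str, np.ndarray],
    segments: StateSegments,
    state: str,
    rate_hz: float,
    min_samples: int = 300,
) -> dict[str, np.ndarray]:
    """Concatenate, in time order, the samples falling inside segments of the
    requested state; identical indexing across regions."""
    n = len(next(iter(traces.values())))
    mask = segments.state_mask(n, rate_hz, state)
    total = int(mask.sum())
    if total < min_samples:
        raise ValueError(
            f"state {state!r} has only {total} samples (< {min_samples} required)"
        )
    return {k: np.asarray(v)[mask] for k, v in traces.items()}


def interregion_spearman(
    series: dict[str, np.ndarray], cell_type: str = "", state: str = ""
) -> ConnectivityMatrix:
    """Pairwise Spearman rank correlation (average ranks on ties)."""
    regions = list(series)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise ValueError("series must have equal lengths")
    k = len(regions)
    r = np.eye(k)
    undefined = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = series[regions[i]], series[regions[j]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                undefined[i, j] = undefined[j, i] = True
                continue
            rho = sps.spearmanr(x, y).statistic
            r[i, j] = r[j, i] = rho
    return ConnectivityMatrix(
        r=r,
        regions=regions,
        cell_type=cell_type,
        state=state,
        n_samples=lengths.pop(),
        undefined=undefined,
    )


def astro_neuron_crosscorr(
    astro_z: np.ndarray,
    neuron_z: np.ndarray,
    max_lag_s: float,
    rate_hz: float,
    state: str = "",
    region: str = "",
) -> CrossCorrResult:
    """Pearson correlation of the overlapping segments at each integer-sample
    lag in [-max_lag, +max_lag]; positive lag means astro follows neuron."""
    x = np.asarray(astro_z, dtype=float)
    y = np.asarray(neuron_z, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal lengths")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: cross-correlation undefined")
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be non-negative")
    max_lag = int(round(max_lag_s * rate_hz))
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    n = len(x)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[:n + lag], y[-lag:]
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            r[k] = np.nan
            continue
        r[k] = np.corrcoef(a, b)[0, 1]
    return CrossCorrResult(lags_s=lags / rate_hz, r_at_lag=r, state=state, region=region)


def build_graph(
    matrix: ConnectivityMatrix,
    coords: dict[str, tuple[float, float]] | None = None,
) -> ConnectivityGraph:
    """Edge list weighted by r; node positions are stereotaxic (AP, ML) mm."""
    coords = coords or REGION_COORDS_MM
    missing = [reg for reg in matrix.regions if reg not in coords]
    if missing:
        raise ValueError(f"missing coordinates for regions: {missing}")
    edges = []
    for i, a in enumerate(matrix.regions):
        for j in range(i + 1, len(matrix.regions)):
            edges.append((a, matrix.regions[j], float(matrix.r[i, j])))
    return ConnectivityGraph(
        nodes={reg: coords[reg] for reg in matrix.regions},
        edges=edges,
        state=matrix.state,
        cell_type=matrix.cell_type,
    )


def state_contrast(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool = False
) -> dict:
    """Group means +/- SEM and the appropriate Wilcoxon test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired contrast requires equal group sizes")
        test: StatResult = wilcoxon_signed_rank(a - b)
    else:
        test = wilcoxon_rank_sum(a, b)
    ma, sa, na = summarize_mean_sem(a)
    mb, sb, nb = summarize_mean_sem(b)
    return {
        "mean_a": ma, "sem_a": sa, "n_a": na,
        "mean_b": mb, "sem_b": sb, "n_b": nb,
        "test": test,
    }
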