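"""Effective connectivity: MVAR models, partial directed coherence, graphs.

A multivariate autoregressive (MVAR) model
``x_t = sum_r A_r x_{t-r} + u_t`` is fitted to the 8-region time series by
pooled least squares across trials.  Partial directed coherence (PDC) is the
column-normalized frequency-domain representation of the coefficients
(Baccala & Sameshima 2001):

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)
    pdc(i, j, f) = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2)

so that ``sum_i pdc(i,j,f)^2 = 1`` for every source j and frequency f.
Band-averaged PDC matrices are thresholded to directed graphs on which
per-node clustering coefficients (Fagiolo's directed generalization by
default) quantify local information-processing efficiency; Go and Nogo are
compared with paired t-tests and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .erp import paired_effect
from .montage import REGIONS
from .preprocess import RegionEpochSet

__all__ = [
    "MVARModel", "PDCNetwork",
    "fit_mvar", "simulate_mvar", "pdc", "band_average", "window_networks",
    "threshold_adjacency", "clustering_coefficients", "compare_conditions",
    "NETWORK_WINDOWS",
]

#: Analysis windows for the information-processing stage, seconds
#: post-event: 350-600 ms for visual sessions, 650-900 ms for auditory.
NETWORK_WINDOWS: dict[str, tuple[float, float]] = {
    "visual": (0.35, 0.60),
    "auditory": (0.65, 0.90),
}


@dataclass(frozen=True)
class MVARModel:
    """Fitted MVAR(p): coefficient matrices, residual covariance, fs."""

    order: int
    coefs: np.ndarray              # (p, k, k)
    resid_cov: np.ndarray          # (k, k)
    fs: float
    stable: bool = True
    portmanteau_p: float | None = None

    @property
    def n_series(self) -> int:
        return self.coefs.shape[1]


@dataclass(frozen=True)
class PDCNetwork:
    """Frequency-resolved directed-coherence tensor plus graph summaries.

    ``pdc[i, j, f]`` is the influence j -> i at ``freqs[f]``, in [0, 1].
    """

    pdc: np.ndarray
    freqs: np.ndarray
    nodes: tuple[str, ...] = REGIONS
    band_summary: np.ndarray | None = None
    band: tuple[float, float] | None = None
    adjacency: np.ndarray | None = None
    window: tuple[float, float] | None = None


def _companion_stable(coefs: np.ndarray) -> bool:
    p, k, _ = coefs.shape
    comp = np.zeros((k * p, k * p))
    comp[:k] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def fit_mvar(region_data: np.ndarray, order: int | None = None,
             fs: float = 250.0, max_order: int = 10) -> MVARModel:
    """Least-squares MVAR fit pooling trials (per-trial mean removed).

    ``region_data`` is trials x k x samples (a single k x samples array is
    treated as one trial).  When ``order`` is None it is chosen by an
    Akaike-style criterion over 1..max_order.  An unstable or singular fit
    is flagged via ``stable`` rather than silently accepted.
    """
    X = np.asarray(region_data, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if order is not None and order < 1:
        raise ValueError("order must be >= 1")
    n_trials, k, n_samp = X.shape
    X = X - X.mean(axis=-1, keepdims=True)

    def _fit(p: int) -> tuple[np.ndarray, np.ndarray, int]:
        if n_samp <= p * k:
            raise ValueError(f"trials too short for order {p} with {k} "
                             "series")
        ys, zs = [], []
        for trial in X:
            ys.append(trial[:, p:])
            zs.append(np.concatenate([trial[:, p - r:n_samp - r]
                                      for r in range(1, p + 1)], axis=0))
        Y = np.concatenate(ys, axis=1)          # (k, N)
        Z = np.concatenate(zs, axis=1)          # (k*p, N)
        B = np.linalg.lstsq(Z.T, Y.T, rcond=None)[0].T   # (k, k*p)
        resid = Y - B @ Z
        n_eff = Y.shape[1]
        sigma = resid @ resid.T / max(n_eff - k * p, 1)
        coefs = B.reshape(k, p, k).transpose(1, 0, 2)
        return coefs, sigma, n_eff

    if order is None:
        best = None
        for p in range(1, max_order + 1):
            if n_samp <= p * k + 1:
                break
            coefs, sigma, n_eff = _fit(p)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                logdet = -np.inf
            aic = logdet + 2.0 * p * k * k / n_eff
            if best is None or aic < best[0]:
                best = (aic, p, coefs, sigma)
        if best is None:
            raise ValueError("no admissible model order")
        _, order, coefs, sigma = best
    else:
        coefs, sigma, _ = _fit(order)

    stable = _companion_stable(coefs) and np.all(np.isfinite(sigma))
    return MVARModel(order=order, coefs=coefs, resid_cov=sigma, fs=fs,
                     stable=stable)


def simulate_mvar(coefs: np.ndarray, n_trials: int, n_samples: int,
                  noise_cov: np.ndarray | None = None,
                  seed: int | np.random.SeedSequence = 0,
                  fs: float = 250.0, burn_in: int = 100) -> np.ndarray:
    """Simulate trials x k x samples from a stable MVAR process."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.ndim == 2:
        coefs = coefs[None]
    p, k, _ = coefs.shape
    if not _companion_stable(coefs):
        raise ValueError("requested MVAR process is unstable")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(noise_cov) if noise_cov is not None else np.eye(k)
    total = n_samples + burn_in
    out = np.empty((n_trials, k, n_samples))
    for tr in range(n_trials):
        x = np.zeros((k, total))
        u = L @ rng.standard_normal((k, total))
        for t in range(p, total):
            x[:, t] = u[:, t]
            for r in range(1, p + 1):
                x[:, t] += coefs[r - 1] @ x[:, t - r]
        out[tr] = x[:, burn_in:]
    return out


def pdc(model: MVARModel, freqs) -> PDCNetwork:
    """Partial directed coherence of a fitted MVAR model.

    Column-normalized (original Baccala-Sameshima convention); the diagonal
    is retained in the tensor and excluded later at the thresholding step.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = model.n_series
    p = model.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / model.fs)
    A_f = np.eye(k)[None] - np.einsum("fr,rij->fij", z, model.coefs)
    mag = np.abs(A_f)                            # (F, k, k)
    denom = np.sqrt((mag**2).sum(axis=1))        # (F, k) per column j
    if np.any(denom <= 0):
        raise ValueError("degenerate model: zero column norm in Abar(f)")
    out = (mag / denom[:, None, :]).transpose(1, 2, 0)   # (k, k, F)
    return PDCNetwork(pdc=out, freqs=freqs,
                      nodes=tuple(f"x{i}" for i in range(k)) if k != 8
                      else REGIONS)


def band_average(net: PDCNetwork, band: tuple[float, float] = (1.0, 6.0)
                 ) -> PDCNetwork:
    """Average the PDC tensor over the stated frequency band."""
    sel = (net.freqs >= band[0]) & (net.freqs <= band[1])
    if not sel.any():
        raise ValueError("band contains no frequency-grid points")
    return replace(net, band_summary=net.pdc[:, :, sel].mean(axis=-1),
                   band=band)


def window_networks(repochs: RegionEpochSet,
                    windows="visual",
                    band: tuple[float, float] = (1.0, 6.0),
                    condition: str = "go",
                    order: int | None = None,
                    n_freqs: int = 16,
                    length: float = 0.2, shift: float = 0.1
                    ) -> list[PDCNetwork]:
    """Band-averaged PDC networks per analysis window for one condition.

    ``windows`` may be a preset name ('visual' -> 350-600 ms,
    'auditory' -> 650-900 ms, 'sliding' -> 200/100 ms windows) or an
    explicit list of (t_lo, t_hi) pairs.
    """
    if isinstance(windows, str):
        if windows in NETWORK_WINDOWS:
            win_list = [NETWORK_WINDOWS[windows]]
        elif windows == "sliding":
            t_end = repochs.tmin + repochs.data.shape[-1] / repochs.fs
            t = repochs.tmin
            win_list = []
            while t + length <= t_end + 1e-9:
                win_list.append((round(t, 9), round(t + length, 9)))
                t += shift
        else:
            raise ValueError(f"unknown window preset {windows!r}")
    else:
        win_list = list(windows)
    data = repochs.kept(condition)
    if data.shape[0] == 0:
        raise ValueError(f"no kept trials of condition {condition!r}")
    times = repochs.times
    freqs = np.linspace(band[0], band[1], n_freqs)
    nets = []
    for t_lo, t_hi in win_list:
        sel = (times >= t_lo - 1e-9) & (times < t_hi - 1e-9)
        if not sel.any():
            raise ValueError(f"window ({t_lo}, {t_hi}) outside the epoch")
        model = fit_mvar(data[:, :, sel], order=order, fs=repochs.fs)
        net = band_average(pdc(model, freqs), band)
        nets.append(replace(net, window=(t_lo, t_hi),
                            nodes=tuple(repochs.labels())))
    return nets


def threshold_adjacency(net: PDCNetwork, method: str = "proportional",
                        q: float = 0.3, cutoff: float | None = None,
                        weighted: bool = False) -> PDCNetwork:
    """Derive an adjacency matrix from the band summary.

    ``proportional`` keeps the top ``round(q * k * (k-1))`` off-diagonal
    edges (fixed density, so clustering comparisons across conditions are
    not confounded by density); ``absolute`` keeps edges above ``cutoff``.
    The diagonal is always excluded.
    """
    if net.band_summary is None:
        raise ValueError("band_summary not computed; call band_average first")
    W = net.band_summary.copy()
    k = W.shape[0]
    np.fill_diagonal(W, 0.0)
    if method == "proportional":
        if not 0.0 < q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        n_edges = int(round(q * k * (k - 1)))
        off = [(W[i, j], i, j) for i in range(k) for j in range(k) if i != j]
        off.sort(key=lambda e: (-e[0], e[1], e[2]))
        adj = np.zeros_like(W)
        for w, i, j in off[:n_edges]:
            adj[i, j] = w if weighted else 1.0
    elif method == "absolute":
        if cutoff is None:
            raise ValueError("absolute thresholding needs a cutoff")
        adj = np.where(W > cutoff, W if weighted else 1.0, 0.0)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return replace(net, adjacency=adj)


def clustering_coefficients(adjacency: np.ndarray,
                            kind: str = "directed") -> np.ndarray:
    """Per-node clustering coefficients of a (binarized) adjacency matrix.

    ``directed`` uses Fagiolo's all-motif directed definition,
    ``undirected`` the Watts-Strogatz coefficient on the symmetrized graph.
    Weighted matrices are binarized unless ``kind='weighted'`` (Fagiolo's
    weighted directed form).  Nodes with fewer than 2 neighbours get 0.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(A) != 0):
        raise ValueError("self-loops are not allowed")
    if kind in ("directed", "undirected"):
        A = (A > 0).astype(float)
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    if kind == "undirected":
        cc = nx.clustering(G.to_undirected())
    elif kind in ("directed", "weighted"):
        cc = nx.clustering(G, weight="weight" if kind == "weighted" else None)
    else:
        raise ValueError(f"unknown clustering kind {kind!r}")
    return np.array([cc[i] for i in range(A.shape[0])])


def compare_conditions(go_values: np.ndarray, nogo_values: np.ndarray,
                       nodes: tuple[str, ...] = REGIONS,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Paired Go-vs-Nogo comparison of per-node metrics across subjects.

    ``go_values``/``nogo_values`` are subjects x nodes arrays of paired
    per-subject metrics.  Returns one row per node with group means +/- SD,
    the two-sided paired-t p value, Cohen's d (pooled-SD form) and a
    significance flag at ``alpha``.
    """
    go = np.asarray(go_values, dtype=float)
    nogo = np.asarray(nogo_values, dtype=float)
    if go.shape != nogo.shape or go.ndim != 2:
        raise ValueError("inputs must be paired subjects x nodes arrays")
    if go.shape[1] != len(nodes):
        raise ValueError("node labels do not match the metric columns")
    rows = []
    for j, node in enumerate(nodes):
        res = paired_effect(go[:, j], nogo[:, j])
        rows.append({
            "region": node,
            "go_mean": res.mean_a, "go_sd": res.sd_a,
            "nogo_mean": res.mean_b, "nogo_sd": res.sd_b,
            "t": res.t_statistic, "p": res.p_value,
            "cohens_d": res.cohens_d,
            "significant": bool(res.p_value < alpha),
        })
    return pd.DataFrame(rows)
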