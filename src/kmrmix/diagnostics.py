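"""Convergence monitoring: traces, the Gelman-Rubin diagnostic, and
posterior summary tables.

The potential scale reduction factor (PSRF) uses the classic form

    PSRF = sqrt( ((L - 1)/L * W + B/L) / W )

with W the mean within-chain variance and B the between-chain variance of
the chain means (times L), computed from >= 2 chains of equal length L.
Values near 1 indicate the chains are sampling the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .samples import PosteriorSamples

__all__ = [
    "TraceBundle",
    "extract_traces",
    "gelman_rubin",
    "posterior_estimates",
    "plot_traces",
]


@dataclass
class TraceBundle:
    """Named parameter traces from one or more chains of equal length."""

    traces: dict[str, np.ndarray]  # name -> (n_chains, L)

    def __post_init__(self) -> None:
        lengths = {arr.shape for arr in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must share chain count and length")

    @property
    def n_chains(self) -> int:
        first = next(iter(self.traces.values()))
        return first.shape[0]

    @property
    def length(self) -> int:
        first = next(iter(self.traces.values()))
        return first.shape[1]


def extract_traces(
    samples: PosteriorSamples | list[PosteriorSamples],
    names: list[str] | None = None,
) -> TraceBundle:
    """Pull ordered traces for the named scalar parameters.

    Names follow the samples-table schema (``beta.1``, ``sigma2``, ``lam``,
    ``r.3``, ``delta.2``, ``tau_b2``). Several chains may be passed as a
    list; they must have equal stored length.
    """
    chains = samples if isinstance(samples, list) else [samples]
    frames = [c.to_frame() for c in chains]
    available = list(frames[0].columns)
    if names is None:
        names = available
    unknown = [n for n in names if n not in available]
    if unknown:
        raise KeyError(
            f"unknown parameter name(s) {unknown}; available: {available}"
        )
    return TraceBundle(
        {n: np.vstack([f[n].to_numpy(float) for f in frames]) for n in names}
    )


def _psrf(chains: np.ndarray) -> float:
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    C, L = chains.shape
    if C < 2:
        raise ValueError("the Gelman-Rubin diagnostic needs at least 2 chains")
    if L < 10:
        raise ValueError("chains must have length >= 10")
    W = chains.var(axis=1, ddof=1).mean()
    B = L * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0  # identical degenerate chains
    # clamp at 1: values below 1 can only arise from the finite-sample
    # (L-1)/L factor (e.g. B = 0 for identical chains)
    return float(max(1.0, np.sqrt(((L - 1) / L * W + B / L) / W)))


def gelman_rubin(
    traces: TraceBundle | np.ndarray | list[np.ndarray],
) -> pd.Series | float:
    """PSRF per parameter (TraceBundle) or for one (n_chains, L) array."""
    if isinstance(traces, TraceBundle):
        return pd.Series(
            {name: _psrf(arr) for name, arr in traces.traces.items()},
            name="psrf",
        )
    if isinstance(traces, list):
        traces = np.vstack([np.asarray(t, float) for t in traces])
    return _psrf(traces)


def posterior_estimates(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, sd and {2.5, 25, 50, 75, 97.5}% quantiles per scalar
    parameter of the stored chain."""
    frame = samples.to_frame()
    if frame.empty:
        raise ValueError("no stored samples")
    arr = frame.to_numpy(float)
    qs = [0.025, 0.25, 0.50, 0.75, 0.975]
    out = {
        "parameter": list(frame.columns),
        # plug-in (empirical-CDF) moments and quantiles: invariant under
        # duplicating the stored chain
        "mean": arr.mean(axis=0),
        "sd": arr.std(axis=0, ddof=0),
    }
    for q in qs:
        out[f"q{100 * q:g}%"] = np.quantile(arr, q, axis=0, method="inverted_cdf")
    return pd.DataFrame(out)


def plot_traces(samples, names: list[str], path=None):
    """Quick trace-plot helper (one panel per parameter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle = extract_traces(samples, names)
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        for chain in bundle.traces[name]:
            ax.plot(chain, lw=0.6)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("stored iteration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
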