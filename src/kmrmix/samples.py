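"""Posterior sample container with persistence.

A :class:`PosteriorSamples` bundles the thinned post-burn-in draws with the
dataset context (standardized exposures, standardization constants, knots)
needed to predict the exposure-response surface at new points. It persists
as a plain-text directory: ``samples.csv`` (one row per stored state),
``data.csv``, ``metadata.json`` and optionally ``knots.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import Workspace
from .data import MixtureDataset
from .params import GroupSpec

__all__ = ["PosteriorSamples"]

_META_NAME = "metadata.json"


@dataclass
class PosteriorSamples:
    """Ordered post-burn-in, thinned MCMC states plus fit context.

    Array shapes use S = number of stored states, P = covariates,
    M = exposures, n = observations. ``data.Z`` is stored on the
    standardized scale; ``Z_orig`` undoes the standardization.
    """

    beta: np.ndarray  # (S, P)
    sigma2: np.ndarray  # (S,)
    lam: np.ndarray  # (S,)
    r: np.ndarray  # (S, M)
    delta: np.ndarray  # (S, M)
    data: MixtureDataset
    centers: np.ndarray
    scales: np.ndarray
    seed: int
    control: dict
    acceptance: dict
    varsel: bool
    tau_b2: np.ndarray | None = None  # (S,)
    y_star: np.ndarray | None = None  # (S, n)
    knots: np.ndarray | None = None
    nugget: float = 1e-6
    groups: GroupSpec | None = None
    _ws: Workspace | None = field(default=None, repr=False, compare=False)

    # -- basic properties -------------------------------------------------
    @property
    def n_states(self) -> int:
        return int(self.beta.shape[0])

    @property
    def M(self) -> int:
        return self.data.M

    @property
    def family(self) -> str:
        return self.data.family

    @property
    def Z_orig(self) -> np.ndarray:
        return self.data.Z * self.scales + self.centers

    def workspace(self) -> Workspace:
        if self._ws is None:
            self._ws = Workspace(self.data, knots=self.knots, nugget=self.nugget)
        return self._ws

    def response(self, s: int) -> np.ndarray:
        """Per-state response vector: y, or the latent y* for probit fits."""
        if self.family == "binomial-probit":
            return self.y_star[s]
        return self.data.y

    def lam_b(self, s: int) -> float | None:
        if self.tau_b2 is None:
            return None
        return float(self.tau_b2[s] / self.sigma2[s])

    # -- tabular view ------------------------------------------------------
    def to_frame(self, include_y_star: bool = False) -> pd.DataFrame:
        """Samples as a table with columns beta.j, sigma2, lam, r.m, delta.m,
        tau_b2 (1-based indices)."""
        cols: dict[str, np.ndarray] = {}
        for j in range(self.beta.shape[1]):
            cols[f"beta.{j + 1}"] = self.beta[:, j]
        cols["sigma2"] = self.sigma2
        cols["lam"] = self.lam
        for m in range(self.M):
            cols[f"r.{m + 1}"] = self.r[:, m]
        for m in range(self.M):
            cols[f"delta.{m + 1}"] = self.delta[:, m]
        if self.tau_b2 is not None:
            cols["tau_b2"] = self.tau_b2
        if include_y_star and self.y_star is not None:
            for i in range(self.y_star.shape[1]):
                cols[f"ystar.{i + 1}"] = self.y_star[:, i]
        return pd.DataFrame(cols)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_frame(include_y_star=True).to_csv(path / "samples.csv", index=False)

        d = self.data
        tab = {d.outcome_name: d.y}
        for j, name in enumerate(d.exposure_names):
            tab[f"z:{name}"] = d.Z[:, j]
        for j, name in enumerate(d.covariate_names):
            tab[f"x:{name}"] = d.X[:, j]
        if d.cluster_id is not None:
            tab["cluster"] = d.cluster_id
        pd.DataFrame(tab).to_csv(path / "data.csv", index=False)

        if self.knots is not None:
            pd.DataFrame(self.knots, columns=d.exposure_names).to_csv(
                path / "knots.csv", index=False
            )
        meta = {
            "seed": int(self.seed),
            "control": self.control,
            "acceptance": self.acceptance,
            "varsel": bool(self.varsel),
            "family": d.family,
            "outcome": d.outcome_name,
            "exposures": d.exposure_names,
            "covariates": d.covariate_names,
            "clustered": d.cluster_id is not None,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "nugget": float(self.nugget),
            "groups": None if self.groups is None
            else {k: list(v) for k, v in self.groups.groups.items()},
        }
        (path / _META_NAME).write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        path = Path(path)
        meta = json.loads((path / _META_NAME).read_text())
        tab = pd.read_csv(path / "data.csv", float_precision="round_trip")
        exposures = meta["exposures"]
        covariates = meta["covariates"]
        data = MixtureDataset(
            y=tab[meta["outcome"]].to_numpy(float),
            Z=tab[[f"z:{c}" for c in exposures]].to_numpy(float),
            X=tab[[f"x:{c}" for c in covariates]].to_numpy(float)
            if covariates
            else np.zeros((len(tab), 0)),
            cluster_id=tab["cluster"].to_numpy() if meta["clustered"] else None,
            family=meta["family"],
            exposure_names=list(exposures),
            covariate_names=list(covariates),
            outcome_name=meta["outcome"],
        )
        frame = pd.read_csv(path / "samples.csv", float_precision="round_trip")
        M = len(exposures)
        P = len(covariates)
        beta = frame[[f"beta.{j + 1}" for j in range(P)]].to_numpy(float) \
            if P else np.zeros((len(frame), 0))
        ystar_cols = [c for c in frame.columns if c.startswith("ystar.")]
        knots = None
        if (path / "knots.csv").exists():
            knots = pd.read_csv(path / "knots.csv").to_numpy(float)
        groups = None
        if meta.get("groups"):
            groups = GroupSpec({k: tuple(v) for k, v in meta["groups"].items()})
        return cls(
            beta=beta,
            sigma2=frame["sigma2"].to_numpy(float),
            lam=frame["lam"].to_numpy(float),
            r=frame[[f"r.{m + 1}" for m in range(M)]].to_numpy(float),
            delta=frame[[f"delta.{m + 1}" for m in range(M)]].to_numpy(int),
            data=data,
            centers=np.asarray(meta["centers"], float),
            scales=np.asarray(meta["scales"], float),
            seed=int(meta["seed"]),
            control=meta["control"],
            acceptance=meta["acceptance"],
            varsel=bool(meta["varsel"]),
            tau_b2=frame["tau_b2"].to_numpy(float) if "tau_b2" in frame else None,
            y_star=frame[ystar_cols].to_numpy(float) if ystar_cols else None,
            knots=knots,
            nugget=float(meta["nugget"]),
            groups=groups,
        )
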