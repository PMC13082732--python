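"""Run configuration and the ChainDraws container with CSV/JSON persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .model import ModelFrame, ModelSpec, ParameterState


@dataclass
class RunConfig:
    """Chain-length bookkeeping.  ``n_iterations`` is the total per chain,
    of which the first ``burn_in`` are discarded; every ``thinning``-th of
    the remainder is kept."""

    n_chains: int = 4
    n_iterations: int = 3000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise InvalidArgumentError("n_chains must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise InvalidArgumentError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise InvalidArgumentError("thinning must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in + self.thinning - 1) // self.thinning

    def chain_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.n_chains)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_chains": self.n_chains,
            "n_iterations": self.n_iterations,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "seed": self.seed,
        }


@dataclass
class ChainDraws:
    """Kept draws on the constrained scale: (chain, iteration, parameter)."""

    draws: np.ndarray
    param_names: list[str]
    sampler: str
    run: RunConfig
    stats: dict[str, Any] = field(default_factory=dict)
    spec_dict: dict[str, Any] | None = None
    data_digest: str | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise InvalidArgumentError("draws must be (chains, iterations, params)")
        if self.draws.shape[2] != len(self.param_names):
            raise InvalidArgumentError("parameter-name count mismatch")
        if not np.all(np.isfinite(self.draws)):
            raise InvalidArgumentError("draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    @property
    def n_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(chains, iterations) matrix for one named parameter."""
        try:
            j = self.param_names.index(name)
        except ValueError as exc:
            raise KeyError(name) from exc
        return self.draws[:, :, j]

    @property
    def stacked(self) -> np.ndarray:
        """(S, P) with chains concatenated."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def spec(self) -> ModelSpec:
        if self.spec_dict is None:
            raise InvalidArgumentError("draws carry no model spec")
        return ModelSpec.from_dict(self.spec_dict)

    def states(self, frame: ModelFrame) -> Iterator[ParameterState]:
        for row in self.stacked:
            yield frame.row_to_state(row)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            pd.DataFrame(self.draws[c], columns=self.param_names).to_csv(
                d / f"chain_{c}.csv", index=False, float_format="%.17g"
            )
        meta = {
            "sampler": self.sampler,
            "run": self.run.to_dict(),
            "stats": _jsonable(self.stats),
            "param_names": self.param_names,
            "spec": self.spec_dict,
            "data_digest": self.data_digest,
            "n_chains": self.n_chains,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "ChainDraws":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        arrs = [
            pd.read_csv(d / f"chain_{c}.csv", float_precision="round_trip").to_numpy()
            for c in range(meta["n_chains"])
        ]
        return cls(
            draws=np.stack(arrs),
            param_names=meta["param_names"],
            sampler=meta["sampler"],
            run=RunConfig(**meta["run"]),
            stats=meta.get("stats", {}),
            spec_dict=meta.get("spec"),
            data_digest=meta.get("data_digest"),
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
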