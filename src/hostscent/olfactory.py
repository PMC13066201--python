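"""Random peripheral-olfactory-system models.

One model is a small set of olfactory-receptor (OR) units.  Each OR is
sensitive to a fixed number of compounds drawn without replacement from the
compound universe (independently across ORs, so a compound may drive several
ORs or none).  Each (OR, compound) pair carries a sensitivity threshold t
drawn uniformly over the 5-log-unit dose range and a dynamic-range width w
drawn log-normally with mean 3 and standard deviation 1 on the natural scale
of w.  Activation of an OR by a compound at a given log dose is the clamped
linear ramp (dose - t) / w; compound activations within an OR combine as
1 - prod(1 - x), keeping OR activity in [0, 1]; the antennal (EAG) response
is the plain sum of OR activities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORTuning",
    "OlfactoryModel",
    "lognormal_width_params",
    "sample_model",
    "activation",
    "or_activity",
    "eag_response",
    "eag_responses",
    "or_response_matrix",
    "detected_set",
    "single_compound_response",
    "single_compound_responses",
]

DOSE_LO, DOSE_HI = 0.0, 5.0
WIDTH_MEAN, WIDTH_SD = 3.0, 1.0


def lognormal_width_params(mean: float = WIDTH_MEAN,
                           sd: float = WIDTH_SD) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a log-normal with the given
    natural-scale mean and standard deviation.

    Reading "mean 3, sd 1" as the parameters of the underlying normal would
    give widths with mean exp(3 + 1/2) ~ 33 log units — far beyond the whole
    5-log-unit dose range — so the natural-scale reading is used.
    """
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass
class ORTuning:
    """Tuning of one OR: detected compounds with per-pair ramp parameters."""

    or_id: int
    compound_ids: np.ndarray  # object array of ids, no duplicates
    thresholds: np.ndarray  # in [0, 5]
    widths: np.ndarray  # > 0


@dataclass
class OlfactoryModel:
    """One random peripheral olfactory system."""

    model_id: int
    universe: pd.Index  # compound universe the ORs draw from
    idx: np.ndarray  # (n_ors, k) positions into universe
    thresholds: np.ndarray  # (n_ors, k)
    widths: np.ndarray  # (n_ors, k)
    seed: object = None

    @property
    def n_ors(self) -> int:
        return self.idx.shape[0]

    @property
    def compounds_per_or(self) -> int:
        return self.idx.shape[1]

    @property
    def ors(self) -> list[ORTuning]:
        ids = np.asarray(self.universe)
        return [ORTuning(i, ids[self.idx[i]], self.thresholds[i],
                         self.widths[i]) for i in range(self.n_ors)]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model_id": self.model_id,
            "seed": self.seed,
            "universe": list(map(str, self.universe)),
            "ors": [{"or_id": i,
                     "compounds": [str(self.universe[j]) for j in self.idx[i]],
                     "thresholds": self.thresholds[i].tolist(),
                     "widths": self.widths[i].tolist()}
                    for i in range(self.n_ors)],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "OlfactoryModel":
        text = str(text_or_path)
        if "{" not in text:  # a path, not a JSON payload
            text = Path(text).read_text()
        payload = json.loads(text)
        universe = pd.Index(payload["universe"])
        pos = {c: i for i, c in enumerate(universe)}
        idx = np.array([[pos[c] for c in o["compounds"]]
                        for o in payload["ors"]])
        t = np.array([o["thresholds"] for o in payload["ors"]])
        w = np.array([o["widths"] for o in payload["ors"]])
        return cls(payload["model_id"], universe, idx, t, w, payload["seed"])


def sample_model(n_ors: int, compounds_per_or: int,
                 universe: Sequence[str] | pd.Index,
                 rng: np.random.Generator,
                 model_id: int = 0) -> OlfactoryModel:
    """Draw one random model: OR-compound assignments, thresholds, widths."""
    universe = pd.Index(universe)
    if compounds_per_or > len(universe):
        raise ValueError("compounds_per_or exceeds the compound universe")
    idx = np.stack([rng.choice(len(universe), size=compounds_per_or,
                               replace=False) for _ in range(n_ors)])
    thresholds = rng.uniform(DOSE_LO, DOSE_HI, size=idx.shape)
    mu, sigma = lognormal_width_params()
    widths = rng.lognormal(mu, sigma, size=idx.shape)
    return OlfactoryModel(model_id, universe, idx, thresholds, widths)


def activation(dose: float | np.ndarray, t: float | np.ndarray,
               w: float | np.ndarray) -> np.ndarray:
    """Clamped linear ramp: 0 below t, 1 above t + w, (dose - t)/w between."""
    return np.clip((np.asarray(dose, float) - t) / w, 0.0, 1.0)


def or_activity(activations: Sequence[float] | np.ndarray) -> float:
    """Combine compound activations of one OR: 1 - prod(1 - x)."""
    x = np.asarray(activations, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("activations must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - x))


def _dose_vector(model: OlfactoryModel,
                 sample: Mapping[str, float]) -> np.ndarray:
    doses = np.full(len(model.universe), -np.inf)  # absent -> zero activation
    pos = {c: i for i, c in enumerate(model.universe)}
    for cid, d in sample.items():
        if cid in pos:
            doses[pos[cid]] = d
    return doses


def eag_response(model: OlfactoryModel, sample: Mapping[str, float]) -> float:
    """Total antennal response to one stimulus: sum of OR activities."""
    doses = _dose_vector(model, sample)
    x = activation(doses[model.idx], model.thresholds, model.widths)
    return float((1.0 - np.prod(1.0 - x, axis=1)).sum())


def or_response_matrix(model: OlfactoryModel,
                       dose_matrix: pd.DataFrame) -> np.ndarray:
    """OR activities for every stimulus row of a dose matrix.

    ``dose_matrix`` is samples x compounds in [0, 5] log units with NaN for
    absent compounds; columns must match the model's universe.  Returns an
    (n_samples, n_ors) array.
    """
    if not dose_matrix.columns.equals(model.universe):
        dose_matrix = dose_matrix.reindex(columns=model.universe)
    d = dose_matrix.to_numpy(float)
    d = np.where(np.isnan(d), -np.inf, d)
    x = activation(d[:, model.idx], model.thresholds[None, :, :],
                   model.widths[None, :, :])
    return 1.0 - np.prod(1.0 - x, axis=2)


def eag_responses(model: OlfactoryModel,
                  dose_matrix: pd.DataFrame) -> np.ndarray:
    """EAG response to every stimulus row of a dose matrix."""
    return or_response_matrix(model, dose_matrix).sum(axis=1)


def detected_set(model: OlfactoryModel) -> set[str]:
    """Compounds detected by the model: union of all ORs' assignments."""
    return set(np.asarray(model.universe)[np.unique(model.idx)])


def single_compound_response(model: OlfactoryModel, compound: str,
                             dose: float) -> float:
    """EAG response to a single-compound stimulus at the given log dose."""
    return eag_response(model, {compound: dose})


def single_compound_responses(model: OlfactoryModel,
                              dose: float) -> pd.Series:
    """EAG response at one dose for every compound in the universe.

    With a single-compound stimulus each OR's activity reduces to that
    compound's ramp activation, so the response is the sum of ramps over the
    ORs sensitive to the compound.  Undetected compounds respond 0.
    """
    x = activation(dose, model.thresholds, model.widths)
    out = np.zeros(len(model.universe))
    np.add.at(out, model.idx.ravel(), x.ravel())
    return pd.Series(out, index=model.universe)
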