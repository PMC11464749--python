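"""Hyperparameter search strategies over declarative parameter domains.

A search space is a mapping ``name -> domain`` where a domain is a
continuous range (optionally log-scaled), an integer range, or a
categorical set. Two strategies share one ask-interface:

* ``RandomSearch`` — independent uniform draws from every domain;
* ``TPESearch`` — a tree-structured Parzen estimator: past trials are
  split by objective into a "good" head (best ``gamma`` fraction) and a
  "bad" tail, each modelled with a Parzen kernel-density mixture; a batch
  of candidates is drawn from the good density and the candidate
  maximizing the density ratio good/bad is proposed. Numeric dimensions
  use Gaussian kernels (in log space when the domain is log-scaled);
  categorical dimensions use smoothed category frequencies.

Both strategies are deterministic given the generator they are driven by.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def contains(self, x) -> bool:
        return isinstance(x, (int, float)) and self.low <= x <= self.high

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class Integer:
    low: int
    high: int

    def contains(self, x) -> bool:
        return float(x) == int(x) and self.low <= int(x) <= self.high

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def contains(self, x) -> bool:
        return x in self.choices

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]


Space = Dict[str, object]
History = List[Tuple[dict, float]]  # (params, mean objective)


def validate_point(space: Space, params: dict) -> None:
    bad = [
        f"{k}={params.get(k)!r} outside domain {space[k]}"
        for k in space
        if k not in params or not space[k].contains(params[k])
    ]
    extra = sorted(set(params) - set(space))
    if extra:
        bad.append(f"unknown hyperparameters {extra}")
    if bad:
        raise ValidationError(bad)


class RandomSearch:
    """Independent uniform sampling from every domain."""

    def suggest(self, rng: np.random.Generator, space: Space, history: History) -> dict:
        return {name: dom.sample(rng) for name, dom in space.items()}


class TPESearch:
    """Sequential model-based sampler using Parzen density ratios."""

    def __init__(self, n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24):
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # -- per-dimension density helpers ------------------------------------

    @staticmethod
    def _to_internal(dom, x) -> float:
        if isinstance(dom, Real) and dom.log:
            return math.log(x)
        return float(x)

    @staticmethod
    def _from_internal(dom, u: float):
        if isinstance(dom, Real):
            x = math.exp(u) if dom.log else u
            return float(min(max(x, dom.low), dom.high))
        # Integer
        return int(min(max(round(u), dom.low), dom.high))

    @staticmethod
    def _bounds(dom) -> Tuple[float, float]:
        if isinstance(dom, Real) and dom.log:
            return math.log(dom.low), math.log(dom.high)
        return float(dom.low), float(dom.high)

    def _numeric_kde(self, dom, obs: Sequence[float]):
        """Parzen mixture: Gaussians at the observations plus a uniform
        prior component over the domain."""
        lo, hi = self._bounds(dom)
        width = hi - lo
        sigma = max(width / math.sqrt(len(obs) + 1), 1e-12)
        obs = np.asarray(obs, dtype=float)

        def pdf(u: float) -> float:
            kernels = np.exp(-0.5 * ((u - obs) / sigma) ** 2) / (
                sigma * math.sqrt(2 * math.pi)
            )
            uniform = 1.0 / width if width > 0 else 1.0
            return (kernels.sum() + uniform) / (len(obs) + 1)

        def draw(rng: np.random.Generator) -> float:
            i = int(rng.integers(len(obs) + 1))
            if i == len(obs):
                return float(rng.uniform(lo, hi))
            return float(rng.normal(obs[i], sigma))

        return pdf, draw

    @staticmethod
    def _cat_probs(dom: Categorical, obs) -> np.ndarray:
        counts = np.ones(len(dom.choices))  # +1 smoothing
        index = {c: i for i, c in enumerate(dom.choices)}
        for o in obs:
            counts[index[o]] += 1
        return counts / counts.sum()

    # -- strategy interface ------------------------------------------------

    def suggest(self, rng: np.random.Generator, space: Space, history: History) -> dict:
        finite = [(p, o) for p, o in history if math.isfinite(o)]
        if len(finite) < self.n_startup:
            return {name: dom.sample(rng) for name, dom in space.items()}

        finite.sort(key=lambda t: t[1])
        n_good = max(1, math.ceil(self.gamma * len(finite)))
        good = [p for p, _ in finite[:n_good]]
        bad = [p for p, _ in finite[n_good:]] or good

        models = {}
        for name, dom in space.items():
            if isinstance(dom, Categorical):
                pg = self._cat_probs(dom, [p[name] for p in good])
                pb = self._cat_probs(dom, [p[name] for p in bad])
                models[name] = ("cat", dom, pg, pb)
            else:
                g_obs = [self._to_internal(dom, p[name]) for p in good]
                b_obs = [self._to_internal(dom, p[name]) for p in bad]
                g_pdf, g_draw = self._numeric_kde(dom, g_obs)
                b_pdf, _ = self._numeric_kde(dom, b_obs)
                models[name] = ("num", dom, (g_pdf, g_draw), b_pdf)

        best_params, best_score = None, -math.inf
        for _ in range(self.n_candidates):
            cand, score = {}, 0.0
            for name, model in models.items():
                if model[0] == "cat":
                    _, dom, pg, pb = model
                    i = int(rng.choice(len(dom.choices), p=pg))
                    cand[name] = dom.choices[i]
                    score += math.log(pg[i]) - math.log(pb[i])
                else:
                    _, dom, (g_pdf, g_draw), b_pdf = model
                    u = g_draw(rng)
                    x = self._from_internal(dom, u)
                    u_clipped = self._to_internal(dom, x)
                    score += math.log(max(g_pdf(u_clipped), 1e-300)) - math.log(
                        max(b_pdf(u_clipped), 1e-300)
                    )
                    cand[name] = x
            if score > best_score:
                best_params, best_score = cand, score
        return best_params


STRATEGIES = {"tpe": TPESearch, "random": RandomSearch}


def get_strategy(name: str):
    if name not in STRATEGIES:
        raise ValidationError(
            f"unknown search strategy {name!r}; registered: {sorted(STRATEGIES)}"
        )
    return STRATEGIES[name]()
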