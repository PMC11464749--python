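"""Seeded synthetic compound tables with known ground truth.

The generator draws molecules from a packaged library of ~1400 valid,
chemically diverse SMILES (with frozen descriptor columns), assigns each a
true potency from a stated descriptor-based model,

    pIC50 = intercept + w_logp * SLogP + w_tpsa * TopoPSA + N(0, noise_sd),

converts it to an nM endpoint (10^(9 - pIC50)), and emits raw CSV rows
with controlled replicate structure: a configurable fraction of compounds
receives extra measurements whose replicate spread (sample SD on the nM
scale) is engineered to fall below — or, for a chosen fraction, above —
the curation inconsistency threshold. The returned ground truth records
every compound's true value, replicate count, engineered group SD and
intended curation fate, so curation behaviour can be checked exactly.

Because activities derive from descriptors the featurizer actually
computes, the signal is recoverable by construction and
parameter-recovery tests are meaningful.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from ._log import log_counts, stage_logger
from .errors import ValidationError

logger = stage_logger("fixtures")

#: Default affine activity model over frozen library descriptors.
DEFAULT_WEIGHTS = {"intercept": 4.0, "slogp": 0.9, "topopsa": -0.02}


@dataclass
class FixtureConfig:
    """Conditions of a synthetic dataset."""

    n_compounds: int = 200
    replicate_rate: float = 0.3       # fraction of compounds with >1 row
    inconsistent_fraction: float = 0.2  # of replicated compounds, over-SD
    noise_sd: float = 0.2             # log units on the true activity
    sd_threshold_nM: float = 100.0    # the curation threshold being exercised
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    class_balance: Optional[float] = None  # target ACTIVE fraction, if any
    seed: int = 0

    def validate(self) -> "FixtureConfig":
        v = []
        if self.n_compounds < 10:
            v.append("n_compounds must be >= 10")
        for name in ("replicate_rate", "inconsistent_fraction"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{name} must lie in [0, 1], got {x}")
        if self.noise_sd < 0:
            v.append("noise_sd must be non-negative")
        if self.sd_threshold_nM <= 0:
            v.append("sd_threshold_nM must be positive")
        if v:
            raise ValidationError(v)
        return self


def load_library() -> pd.DataFrame:
    """The packaged SMILES library with frozen descriptor columns."""
    ref = importlib.resources.files("qsprkit.data") / "smiles_library.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _engineered_replicates(rng: np.random.Generator, base_nM: float,
                           n_rep: int, target_sd_nM: float) -> np.ndarray:
    """Replicate values with sample SD exactly ``target_sd_nM``.

    Deviations are centred and rescaled; if rescaling pushes a value
    non-positive the whole group is shifted up, which preserves the SD.
    """
    z = rng.normal(size=n_rep)
    z = z - z.mean()
    s = z.std(ddof=1)
    if s == 0:  # degenerate draw; fall back to a fixed symmetric pattern
        z = np.linspace(-1.0, 1.0, n_rep)
        z = z - z.mean()
        s = z.std(ddof=1)
    values = base_nM + z / s * target_sd_nM
    if values.min() <= 0:
        values = values + (1e-6 + base_nM * 0.01 - values.min())
    return values


def generate(config: FixtureConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build ``(raw_rows, ground_truth)`` tables.

    ``raw_rows`` has columns ``smiles, value, assay_id`` (values in nM);
    ``ground_truth`` has one row per compound: canonical-library SMILES,
    true plog, true endpoint, replicate count, engineered group SD and
    the intended curation fate (``kept`` / ``removed_inconsistent``).
    """
    config.validate()
    lib = load_library()
    if config.n_compounds > len(lib):
        raise ValidationError(
            f"n_compounds={config.n_compounds} exceeds the library size "
            f"{len(lib)}; resampling of compounds is not supported"
        )
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(lib), size=config.n_compounds, replace=False)
    chosen = lib.iloc[np.sort(pick)].reset_index(drop=True)

    w = config.weights
    true_plog = (
        w["intercept"]
        + w["slogp"] * chosen["slogp"].to_numpy()
        + w["topopsa"] * chosen["topopsa"].to_numpy()
        + rng.normal(0.0, config.noise_sd, size=len(chosen))
    )
    true_nM = 10.0 ** (9.0 - true_plog)

    n = len(chosen)
    n_rep = int(round(config.replicate_rate * n))
    rep_idx = rng.choice(n, size=n_rep, replace=False)
    n_bad = int(round(config.inconsistent_fraction * n_rep))
    bad = set(rep_idx[:n_bad].tolist())
    rep_set = set(rep_idx.tolist())

    rows, truth = [], []
    for i in range(n):
        smi = chosen.loc[i, "smiles"]
        base = float(true_nM[i])
        if i in rep_set:
            k = int(rng.integers(2, 5))
            if i in bad:
                target_sd = config.sd_threshold_nM * float(rng.uniform(1.5, 5.0))
            else:
                # Assay-like spread: small relative to the value and safely
                # below the removal threshold.
                target_sd = min(
                    config.sd_threshold_nM * float(rng.uniform(0.2, 0.8)),
                    base * float(rng.uniform(0.05, 0.2)),
                )
            values = _engineered_replicates(rng, base, k, target_sd)
            fate = "removed_inconsistent" if i in bad else "kept"
            group_sd = float(np.std(values, ddof=1))
        else:
            k, values = 1, np.array([base])
            fate, group_sd = "kept", 0.0
        for j, v in enumerate(values):
            rows.append({"smiles": smi, "value": float(v), "assay_id": f"assay_{i}_{j}"})
        truth.append({
            "smiles": smi,
            "true_plog": float(true_plog[i]),
            "true_value_nM": base,
            "n_replicates": k,
            "group_sd_nM": group_sd,
            "fate": fate,
        })

    raw = pd.DataFrame(rows)
    gt = pd.DataFrame(truth)
    log_counts(
        logger, "generated fixture",
        compounds=n, rows=len(raw),
        replicated=n_rep, flagged_inconsistent=n_bad,
    )
    return raw, gt


def solve_class_threshold(endpoints_nM, target_active_fraction: float) -> float:
    """Threshold (nM) putting ~the target fraction of compounds at or
    below it, i.e. labelled ACTIVE."""
    if not 0.0 < target_active_fraction < 1.0:
        raise ValidationError("target_active_fraction must lie in (0, 1)")
    return float(np.quantile(np.asarray(endpoints_nM), target_active_fraction))


def write_fixture(config: FixtureConfig, raw_path, truth_path) -> None:
    raw, gt = generate(config)
    raw.to_csv(raw_path, index=False)
    gt.to_csv(truth_path, index=False)
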