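"""Raw-data curation: canonical grouping, consistency filtering, aggregation.

Potency databases routinely hold several measurements of the same compound
taken in different assays. Curation proceeds in three steps:

1. **canonicalize** every SMILES (RDKit canonical form, stereo preserved)
   so that all spellings of one structure share a key; unparseable strings
   are dropped and counted;
2. **filter** replicate groups whose spread on the nM scale — sample
   standard deviation by default — strictly exceeds the configured
   inconsistency threshold (100 nM reference default); singletons are
   always retained;
3. **aggregate** each surviving group to a single endpoint with the
   configured strategy (mean, median, min or max).

The standard deviation is taken on the nM concentration scale, before any
log transform, because the threshold is quoted in nM.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem, RDLogger

from ._log import log_counts, stage_logger
from .config import CompoundRecord, TrainingConfig
from .errors import ContractError

RDLogger.DisableLog("rdApp.*")

logger = stage_logger("curation")


@dataclass
class CuratedDataset:
    """One aggregated endpoint per canonical structure, plus a removal audit."""

    records: List[Tuple[str, float]] = field(default_factory=list)
    removed_inconsistent: List[Tuple[str, float]] = field(default_factory=list)
    removed_invalid: int = 0
    aggregation_used: str = "mean"
    n_multifragment: int = 0

    @property
    def smiles(self) -> List[str]:
        return [s for s, _ in self.records]

    @property
    def endpoints_nM(self) -> List[float]:
        return [v for _, v in self.records]


def canonicalize(smiles_raw: str, desalt: bool = False) -> Optional[str]:
    """Canonical SMILES (stereo preserved), or ``None`` if unparseable.

    With ``desalt=True`` only the largest fragment of a multi-fragment
    SMILES is kept before canonicalization.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return None
    if desalt:
        frags = Chem.GetMolFrags(mol, asMols=True)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def group_sd(values: Sequence[float], kind: str = "sample") -> float:
    """Spread of a replicate group in nM; 0.0 for singletons."""
    if len(values) < 2:
        return 0.0
    if kind == "population":
        return statistics.pstdev(values)
    return statistics.stdev(values)


def filter_inconsistent(
    groups: Dict[str, List[float]],
    sd_threshold_nM: float,
    kind: str = "sample",
    strict: bool = True,
):
    """Split groups into (retained, removed-with-SD) by the spread test.

    A group is removed iff its SD exceeds the threshold — strictly by
    default. Singletons always pass.
    """
    retained: Dict[str, List[float]] = {}
    removed: List[Tuple[str, float]] = []
    for key, values in groups.items():
        sd = group_sd(values, kind)
        over = sd > sd_threshold_nM if strict else sd >= sd_threshold_nM
        if len(values) >= 2 and over:
            removed.append((key, sd))
        else:
            retained[key] = values
    return retained, removed


def aggregate(group: Sequence[float], strategy: str) -> float:
    """Collapse a consistent replicate group to one endpoint."""
    if not group:
        raise ContractError("cannot aggregate an empty replicate group")
    if strategy == "mean":
        return float(statistics.fmean(group))
    if strategy == "median":
        return float(statistics.median(group))
    if strategy == "min":
        return float(min(group))
    if strategy == "max":
        return float(max(group))
    raise ContractError(f"unknown aggregation strategy {strategy!r}")


def curate(records: Sequence[CompoundRecord], training_config: TrainingConfig) -> CuratedDataset:
    """Full curation pass: canonicalize → group → SD-filter → aggregate.

    Output records are sorted by canonical SMILES, so the result is
    invariant to the input row order.
    """
    groups: Dict[str, List[float]] = {}
    invalid = 0
    multifrag = 0
    for rec in records:
        can = canonicalize(rec.smiles_raw, desalt=training_config.desalt)
        if can is None:
            invalid += 1
            continue
        if "." in can:
            multifrag += 1
        rec.smiles_canonical = can
        groups.setdefault(can, []).append(rec.endpoint_nM)

    # Sorting each group fixes the summation order, making the output
    # bit-identical under any permutation of the input rows.
    groups = {k: sorted(v) for k, v in groups.items()}
    retained, removed = filter_inconsistent(
        groups,
        training_config.inconsistency_sd_threshold,
        kind=training_config.sd_kind,
        strict=training_config.sd_strict,
    )
    out = CuratedDataset(
        records=sorted(
            (k, aggregate(v, training_config.aggregation)) for k, v in retained.items()
        ),
        removed_inconsistent=sorted(removed),
        removed_invalid=invalid,
        aggregation_used=training_config.aggregation,
        n_multifragment=multifrag,
    )
    log_counts(
        logger,
        "curated",
        input_rows=len(records),
        compounds=len(out.records),
        removed_inconsistent=len(out.removed_inconsistent),
        removed_invalid=invalid,
        multifragment=multifrag,
    )
    return out
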