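"""Structure-based edgotype classification and its validation statistics.

Each mapped mutation first receives a location class: **interfacial** if its
position belongs to any partner's binding interface (interface membership
takes priority over RSA), otherwise **exposed** if RSA > 0.25, otherwise
**buried**.  The edgotype then follows from ddG thresholds:

* **edgetic** — interfacial and at least one partner binding
  ddG > 0.5 kcal/mol (those partners are the disrupted ones);
* **quasi-null** — buried and folding ddG >= 2 kcal/mol;
* **quasi-wild-type** — everything else.

Interfacial mutations are never routed to the quasi-null branch, so the
quasi-null fractions are independent of the binding cutoff.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._tables import HYDROPHOBICITY_KD, MOLECULAR_WEIGHT
from .errors import (
    DegenerateTableError,
    IncompleteGeometryError,
    MissingDdgError,
    NoOverlapError,
    ParseError,
    TableMissError,
)
from .geometry import RSA_BURIAL_CUTOFF
from .labels import (
    BURIED,
    EDGETIC,
    EDGOTYPES,
    EXPOSED,
    INTERFACIAL,
    NONPATHOGENIC,
    PATHOGENIC,
    QUASI_NULL,
    QUASI_WILDTYPE,
)

logger = logging.getLogger(__name__)

BINDING_DDG_CUTOFF = 0.5  # kcal/mol, strict (>)
FOLDING_DDG_CUTOFF = 2.0  # kcal/mol, inclusive (>=)

MutationKey = tuple[str, int, str, str]  # (protein, position, wt, mut)


@dataclass(frozen=True)
class DdgRecord:
    """One ddG value: folding (per mutation) or binding (per partner)."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    kind: str  # "binding" | "folding"
    ddg: float  # kcal/mol
    partner: str | None = None

    def __post_init__(self):
        if self.kind == "binding" and not self.partner:
            raise ValueError("binding records must carry a partner")
        if self.kind == "folding" and self.partner:
            raise ValueError("folding records must not carry a partner")
        if self.kind not in ("binding", "folding"):
            raise ValueError(f"unknown ddG kind {self.kind!r}")

    @property
    def key(self) -> MutationKey:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


@dataclass(frozen=True)
class EdgotypeCall:
    """Location class plus edgotype for one mutation."""

    key: MutationKey
    location: str
    edgotype: str
    disrupted_partners: tuple[str, ...] = ()
    rsa: float | None = None
    folding_ddg: float | None = None

    def __post_init__(self):
        if self.edgotype == EDGETIC and (
            self.location != INTERFACIAL or not self.disrupted_partners
        ):
            raise ValueError("edgetic calls must be interfacial with partners")
        if self.edgotype == QUASI_NULL and self.location != BURIED:
            raise ValueError("quasi-null calls must be buried")


def classify_location(
    position: int,
    interface_positions: set[int] | frozenset[int],
    rsa_value: float | None,
    rsa_cutoff: float = RSA_BURIAL_CUTOFF,
) -> str:
    """Interface membership takes priority; then the RSA burial rule.

    Exposed iff RSA > cutoff; the boundary value is buried.
    """
    if position in interface_positions:
        return INTERFACIAL
    if rsa_value is None or np.isnan(rsa_value):
        raise IncompleteGeometryError(f"no RSA for position {position}")
    return EXPOSED if rsa_value > rsa_cutoff else BURIED


def classify_edgotype(
    key: MutationKey,
    location: str,
    binding_records: Iterable[DdgRecord] = (),
    folding_record: DdgRecord | None = None,
    binding_cutoff: float = BINDING_DDG_CUTOFF,
    folding_cutoff: float = FOLDING_DDG_CUTOFF,
    rsa_value: float | None = None,
) -> EdgotypeCall:
    """Assign an edgotype from location and ddG values.

    Partner order does not affect the call; disrupted partners are reported
    sorted.
    """
    folding_ddg = folding_record.ddg if folding_record is not None else None
    if location == INTERFACIAL:
        binding = sorted(binding_records, key=lambda r: r.partner)
        if not binding:
            raise MissingDdgError(f"interfacial mutation {key} has no binding ddG")
        disrupted = tuple(r.partner for r in binding if r.ddg > binding_cutoff)
        edgotype = EDGETIC if disrupted else QUASI_WILDTYPE
        return EdgotypeCall(key, location, edgotype, disrupted,
                            rsa_value, folding_ddg)
    if location == BURIED:
        if folding_record is None:
            raise MissingDdgError(f"buried mutation {key} has no folding ddG")
        edgotype = QUASI_NULL if folding_record.ddg >= folding_cutoff \
            else QUASI_WILDTYPE
        return EdgotypeCall(key, location, edgotype, (), rsa_value, folding_ddg)
    return EdgotypeCall(key, location, QUASI_WILDTYPE, (), rsa_value, folding_ddg)


def parse_ddg_table(source: str | Path | io.StringIO) -> list[DdgRecord]:
    """Read ddG records from plain TSV or a FoldX-style difference file.

    Plain TSV needs a header with columns ``protein_id position wt_aa mut_aa
    kind partner ddg`` (empty partner for folding rows).  A file whose first
    non-comment line starts with ``Pdb\\t`` is read as a FoldX-style fixture
    dialect: rows of ``<protein>:<wt><position><mut>[:<partner>]`` followed by
    the energy difference; a partner field marks a binding record.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        logger.warning("empty ddG table")
        return []
    if lines[0].startswith("Pdb\t"):
        return _parse_foldx_dialect(lines)
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                     keep_default_na=False)
    required = {"protein_id", "position", "wt_aa", "mut_aa", "kind", "ddg"}
    if not required <= set(df.columns):
        raise ParseError(
            f"ddG table missing columns {sorted(required - set(df.columns))}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ddg = float(row.ddg)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"unparseable ddG value {row.ddg!r}", line=i) from exc
        partner = str(getattr(row, "partner", "") or "")
        records.append(
            DdgRecord(
                protein_id=str(row.protein_id), position=int(row.position),
                wt_aa=str(row.wt_aa), mut_aa=str(row.mut_aa),
                kind=str(row.kind), ddg=ddg, partner=partner or None,
            )
        )
    return records


def _parse_foldx_dialect(lines: list[str]) -> list[DdgRecord]:
    records = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected mutation and energy, got {line!r}", line=i)
        tag, value = fields[0], fields[1]
        try:
            ddg = float(value)
        except ValueError as exc:
            raise ParseError(f"unparseable ddG value {value!r}", line=i) from exc
        parts = tag.split(":")
        if len(parts) not in (2, 3):
            raise ParseError(f"unparseable mutation tag {tag!r}", line=i)
        protein, mut = parts[0], parts[1]
        partner = parts[2] if len(parts) == 3 else None
        wt, pos, mut_aa = mut[0], int(mut[1:-1]), mut[-1]
        records.append(
            DdgRecord(
                protein_id=protein, position=pos, wt_aa=wt, mut_aa=mut_aa,
                kind="binding" if partner else "folding",
                ddg=ddg, partner=partner,
            )
        )
    return records


def group_ddg_records(
    records: Iterable[DdgRecord],
) -> dict[MutationKey, dict[str, object]]:
    """Index ddG records by mutation key into binding lists + folding record."""
    out: dict[MutationKey, dict[str, object]] = {}
    for rec in records:
        slot = out.setdefault(rec.key, {"binding": [], "folding": None})
        if rec.kind == "binding":
            slot["binding"].append(rec)
        else:
            slot["folding"] = rec
    return out


def edgotype_counts(
    calls: Iterable[EdgotypeCall],
    phenotype_labels: Mapping[MutationKey, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2x3 count table (phenotype class x edgotype) and its row fractions."""
    counts = pd.DataFrame(
        0, index=list((NONPATHOGENIC, PATHOGENIC)), columns=list(EDGOTYPES)
    )
    for call in calls:
        cls = phenotype_labels[call.key]
        counts.loc[cls, call.edgotype] += 1
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def enrichment_test(counts: pd.DataFrame) -> tuple[float, float]:
    """Fisher exact test for interactome disruption vs phenotype class.

    Collapses the 2x3 table to (edgetic or quasi-null) vs quasi-wild-type
    against pathogenic vs non-pathogenic; returns (odds ratio, two-sided p).
    """
    disruptive = counts[EDGETIC] + counts[QUASI_NULL]
    table = np.array(
        [
            [disruptive[PATHOGENIC], counts.loc[PATHOGENIC, QUASI_WILDTYPE]],
            [disruptive[NONPATHOGENIC], counts.loc[NONPATHOGENIC, QUASI_WILDTYPE]],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def evaluate_against_experiment(
    predicted: Mapping[MutationKey, str],
    experimental: Mapping[MutationKey, str],
) -> pd.DataFrame:
    """Per-edgotype one-vs-rest TPR/FPR of predictions vs experiments.

    TPR = fraction of experimentally positive mutations predicted positive;
    FPR = fraction of experimentally negative mutations predicted positive.
    Computed on the overlap of mutation keys, separately for the edgetic and
    quasi-null classes, with a two-sided Fisher exact p per class.
    """
    keys = sorted(set(predicted) & set(experimental))
    if not keys:
        raise NoOverlapError("no shared mutation keys")
    rows = []
    for t in (EDGETIC, QUASI_NULL):
        tp = sum(1 for k in keys if predicted[k] == t and experimental[k] == t)
        fn = sum(1 for k in keys if predicted[k] != t and experimental[k] == t)
        fp = sum(1 for k in keys if predicted[k] == t and experimental[k] != t)
        tn = sum(1 for k in keys if predicted[k] != t and experimental[k] != t)
        tpr = tp / (tp + fn) if tp + fn else np.nan
        fpr = fp / (fp + tn) if fp + tn else np.nan
        _, p = stats.fisher_exact([[tp, fn], [fp, tn]], alternative="two-sided")
        rows.append({"edgotype": t, "tpr": tpr, "fpr": fpr, "fisher_p": p,
                     "n_overlap": len(keys)})
    return pd.DataFrame(rows)


def property_change_summary(
    records: pd.DataFrame,
    hydrophobicity: Mapping[str, float] | None = None,
    molecular_weight: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fractions of mutations lowering hydrophobicity / raising weight.

    ``records`` needs columns ``wt_aa, mut_aa, edgotype``; callers pass the
    deleterious (pathogenic) calls.  Default scales: Kyte-Doolittle
    hydropathy and standard residue molecular weights.
    """
    hydro = hydrophobicity if hydrophobicity is not None else HYDROPHOBICITY_KD
    weight = molecular_weight if molecular_weight is not None else MOLECULAR_WEIGHT
    rows = []
    for t, group in records.groupby("edgotype"):
        n = len(group)
        try:
            dh = [hydro[m] - hydro[w] for w, m in zip(group.wt_aa, group.mut_aa)]
            dw = [weight[m] - weight[w] for w, m in zip(group.wt_aa, group.mut_aa)]
        except KeyError as exc:
            raise TableMissError(str(exc)) from exc
        rows.append(
            {
                "edgotype": t,
                "n": n,
                "hydrophobicity_decrease": sum(d < 0 for d in dh) / n,
                "molecular_weight_increase": sum(d > 0 for d in dw) / n,
            }
        )
    return pd.DataFrame(rows).set_index("edgotype")
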