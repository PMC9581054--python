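"""Mutation filtering and mapping onto interactome proteins.

Two mutation sets feed the analysis:

* **pathogenic set** (ClinVar-like): missense variants strictly labelled
  pathogenic, with supporting evidence (>= 1 star) and no conflicting
  interpretations;
* **common set** (dbSNP-like): missense variants that are validated, not
  withdrawn, carry no pathogenic/uncertain-type assertion, and have minor
  allele frequency >= 1%.

Both sets are then verified by flanking-sequence matching (up to 10 residues
each side of the site, truncated at sequence ends, wild-type residue at the
site): a record maps only if the flank occurs at the reported position in
both the transcript and the protein sequence.  Finally one record is kept
per (protein, position) and common records overlapping pathogenic positions
are discarded, so the two classes are disjoint in position space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import CoordinateError, SchemaError

MIN_MAF = 0.01
FLANK_WIDTH = 10

# assertion values excluded from the common set ("pathogenic or uncertain")
EXCLUDED_ASSERTIONS = frozenset(
    {"pathogenic", "likely pathogenic", "drug-response", "drug response",
     "uncertain significance", "other"}
)

CLINVAR_REQUIRED = ("consequence", "significance", "stars", "conflicting")
DBSNP_REQUIRED = ("consequence", "validated", "withdrawn", "assertion", "maf")


@dataclass
class FilterResult:
    """Filtered records plus per-rule rejection counts."""

    records: pd.DataFrame
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.records)


def _require(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns {missing}")


def _norm(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().str.lower()


def filter_clinvar(records: pd.DataFrame) -> FilterResult:
    """Keep missense records strictly labelled pathogenic with evidence.

    Keep iff missense AND significance is exactly ``pathogenic`` AND
    stars >= 1 AND no conflicting-interpretation flag.
    """
    _require(records, CLINVAR_REQUIRED)
    df = records
    rules = {
        "not-missense": _norm(df["consequence"]) != "missense",
        "not-strictly-pathogenic": _norm(df["significance"]) != "pathogenic",
        "no-supporting-evidence": pd.to_numeric(
            df["stars"], errors="coerce"
        ).fillna(0) < 1,
        "conflicting-interpretations": df["conflicting"].fillna(False).astype(bool),
    }
    return _apply_rules(df, rules)


def filter_dbsnp(
    records: pd.DataFrame,
    excluded_assertions: frozenset[str] = EXCLUDED_ASSERTIONS,
    min_maf: float = MIN_MAF,
) -> FilterResult:
    """Keep validated, non-withdrawn common missense records with MAF >= 1%.

    Records with a pathogenic/uncertain-type assertion are discarded;
    records with no MAF are dropped (conservative).
    """
    _require(records, DBSNP_REQUIRED)
    df = records
    maf = pd.to_numeric(df["maf"], errors="coerce")
    rules = {
        "not-missense": _norm(df["consequence"]) != "missense",
        "not-validated": ~df["validated"].fillna(False).astype(bool),
        "withdrawn": df["withdrawn"].fillna(False).astype(bool),
        "pathogenic-or-uncertain-assertion": _norm(df["assertion"]).isin(
            {a.lower() for a in excluded_assertions}
        ),
        "missing-maf": maf.isna(),
        "low-maf": maf.fillna(0) < min_maf,
    }
    return _apply_rules(df, rules)


def _apply_rules(df: pd.DataFrame, rules: dict[str, pd.Series]) -> FilterResult:
    keep = pd.Series(True, index=df.index)
    rejections: dict[str, int] = {}
    for name, bad in rules.items():
        hit = bad & keep  # count each record under the first failing rule
        rejections[name] = int(hit.sum())
        keep &= ~bad
    return FilterResult(records=df[keep].copy(), rejections=rejections)


def flank_window(position: int, seq_length: int, width: int = FLANK_WIDTH):
    """0-based [start, end) window of the flank around a 1-based position."""
    if position < 1 or position > seq_length:
        raise CoordinateError(
            f"position {position} beyond sequence of length {seq_length}"
        )
    start = max(0, position - 1 - width)
    end = min(seq_length, position + width)
    return start, end


def verify_flank(
    position: int,
    wt_aa: str,
    flank: str,
    transcript_seq: str,
    protein_seq: str,
) -> bool:
    """Check a record's flank against transcript and protein sequences.

    The flank (with the wild-type residue at the site) must occur at the
    reported position in the transcript AND at the same position in the
    protein.  Positions beyond either sequence raise
    :class:`CoordinateError`.
    """
    t_start, t_end = flank_window(position, len(transcript_seq))
    flank_window(position, len(protein_seq))  # coordinate check only
    site_offset = position - 1 - t_start
    if site_offset >= len(flank) or flank[site_offset] != wt_aa:
        return False
    if transcript_seq[t_start:t_end] != flank:
        return False
    if protein_seq[t_start:t_end] != flank:
        return False
    return True


def map_mutations(
    records: pd.DataFrame,
    transcripts: dict[str, str],
    proteins: dict[str, str],
) -> FilterResult:
    """Flank-verify each record against its transcript and protein.

    Records whose protein lacks a transcript or protein sequence are
    rejected with reason ``missing-sequence``.
    """
    _require(records, ("protein_id", "position", "wt_aa", "transcript_flank"))
    keep_idx = []
    rejections = {"missing-sequence": 0, "flank-mismatch": 0}
    for idx, row in records.iterrows():
        pid = row["protein_id"]
        if pid not in transcripts or pid not in proteins:
            rejections["missing-sequence"] += 1
            continue
        ok = verify_flank(
            int(row["position"]), row["wt_aa"], row["transcript_flank"],
            transcripts[pid], proteins[pid],
        )
        if ok:
            keep_idx.append(idx)
        else:
            rejections["flank-mismatch"] += 1
    return FilterResult(records=records.loc[keep_idx].copy(),
                        rejections=rejections)


def dedupe_positions(records: pd.DataFrame, policy: str = "first") -> FilterResult:
    """Retain one record per (protein, position).

    ``policy='first'`` keeps the first record in stable input order;
    ``policy='highest_star'`` keeps the record with the most review stars.
    """
    _require(records, ("protein_id", "position"))
    if policy == "first":
        kept = records.drop_duplicates(
            subset=["protein_id", "position"], keep="first"
        )
    elif policy == "highest_star":
        order = pd.to_numeric(records.get("stars", 0), errors="coerce").fillna(0)
        kept = (
            records.assign(_stars=order)
            .sort_values("_stars", ascending=False, kind="stable")
            .drop_duplicates(subset=["protein_id", "position"], keep="first")
            .sort_index()
            .drop(columns="_stars")
        )
    else:
        raise ValueError(f"unknown dedup policy {policy!r}")
    return FilterResult(
        records=kept.copy(),
        rejections={"duplicate-position": len(records) - len(kept)},
    )


def exclude_overlap(
    common: pd.DataFrame, pathogenic: pd.DataFrame
) -> FilterResult:
    """Drop common records sharing (protein, position) with a pathogenic one."""
    _require(common, ("protein_id", "position"))
    _require(pathogenic, ("protein_id", "position"))
    path_keys = set(
        zip(pathogenic["protein_id"], pathogenic["position"].astype(int))
    )
    mask = [
        (pid, int(pos)) not in path_keys
        for pid, pos in zip(common["protein_id"], common["position"])
    ]
    kept = common[mask]
    return FilterResult(
        records=kept.copy(),
        rejections={"overlaps-pathogenic": len(common) - len(kept)},
    )
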