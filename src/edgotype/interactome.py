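"""Structural-interactome assembly: template annotation of reference PPIs.

A reference interactome is a two-column table of protein pairs.  Each PPI is
annotated with a chain-pair template when (1) the two chains share a binding
interface, and (2) each protein aligns to its chain with at least 50% of that
chain's interface residues mapped onto the protein.  Alignments are consumed
from a BLAST-style tabular file (one best alignment per protein/chain pair,
smallest E-value); template interface residues are then transferred onto
protein coordinates through the alignment position maps.

Template coordinates are used directly through the position maps (rather
than rebuilding homology models): every downstream rule operates on residue
positions and template geometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .errors import ParseError

E_VALUE_CUTOFF = 1e-5
MIN_INTERFACE_COVERAGE = 0.5


class InteractionEdge(NamedTuple):
    """Unordered protein pair; construct through :func:`make_edge`."""

    protein_a: str
    protein_b: str


def make_edge(a: str, b: str) -> InteractionEdge:
    a, b = sorted((str(a), str(b)))
    return InteractionEdge(a, b)


def load_interactome(source: str | Path | io.StringIO) -> list[InteractionEdge]:
    """Read a two-column edge table into deduplicated unordered edges.

    Self-interactions are retained.  A header row of ``protein_a\\tprotein_b``
    is accepted; any other malformed row raises :class:`ParseError` with its
    line number.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    edges: set[InteractionEdge] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not all(f.strip() for f in fields):
            raise ParseError(f"expected 2 protein identifiers, got {line!r}",
                             line=lineno)
        if lineno == 1 and fields[0].lower() in ("protein_a", "proteina"):
            continue
        edges.add(make_edge(fields[0].strip(), fields[1].strip()))
    return sorted(edges)


@dataclass(frozen=True)
class AlignmentRecord:
    """One protein-to-chain alignment with its aligned position pairs.

    ``pairs`` holds 1-based (protein_pos, chain_pos) tuples over aligned,
    non-gap columns, strictly increasing in both coordinates.
    """

    protein_id: str
    chain_id: str  # "<structure id>_<chain letter>"
    e_value: float
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("E-value must be >= 0")
        prev = (0, 0)
        for p in self.pairs:
            if not (p[0] > prev[0] and p[1] > prev[1]):
                raise ValueError("position pairs must be strictly increasing")
            prev = p

    def protein_to_chain(self) -> dict[int, int]:
        return {p: c for p, c in self.pairs}

    def chain_to_protein(self) -> dict[int, int]:
        return {c: p for p, c in self.pairs}


def pairs_from_aligned_strings(
    qstart: int, sstart: int, qseq: str, sseq: str
) -> tuple[tuple[int, int], ...]:
    """Aligned position pairs from gapped query/subject alignment strings."""
    if len(qseq) != len(sseq):
        raise ValueError("aligned strings must have equal length")
    pairs = []
    q, s = qstart, sstart
    for qc, sc in zip(qseq, sseq):
        if qc != "-" and sc != "-":
            pairs.append((q, s))
        if qc != "-":
            q += 1
        if sc != "-":
            s += 1
    return tuple(pairs)


def read_alignments(
    source: str | Path | io.StringIO, e_cutoff: float = E_VALUE_CUTOFF
) -> list[AlignmentRecord]:
    """Parse a BLAST-style tabular alignment file.

    Expects columns ``query subject evalue qstart qend sstart send qseq
    sseq``; records above the E-value cutoff are discarded.
    """
    df = pd.read_csv(source, sep="\t", dtype={"query": str, "subject": str})
    required = {"query", "subject", "evalue", "qstart", "sstart", "qseq", "sseq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"alignment table missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = AlignmentRecord(
                protein_id=row.query,
                chain_id=row.subject,
                e_value=float(row.evalue),
                pairs=pairs_from_aligned_strings(
                    int(row.qstart), int(row.sstart), row.qseq, row.sseq
                ),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), line=i) from exc
        if rec.e_value <= e_cutoff:
            records.append(rec)
    return records


def select_best_alignment(
    records: Iterable[AlignmentRecord],
) -> dict[tuple[str, str], AlignmentRecord]:
    """Retain the smallest-E-value alignment per (protein, chain).

    Ties break toward more aligned pairs, then lexicographically smaller
    chain id, then the pair list itself, so selection is deterministic.
    """
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for rec in records:
        key = (rec.protein_id, rec.chain_id)
        cur = best.get(key)
        if cur is None or _rank(rec) < _rank(cur):
            best[key] = rec
    return best


def _rank(rec: AlignmentRecord):
    return (rec.e_value, -len(rec.pairs), rec.chain_id, rec.pairs)


@dataclass(frozen=True)
class ChainPairAnnotation:
    """An accepted PPI template: chain pair, coverages, position maps."""

    edge: InteractionEdge
    chain_a: str  # template chain aligned to edge.protein_a
    chain_b: str
    coverage_a: float
    coverage_b: float
    alignment_a: AlignmentRecord
    alignment_b: AlignmentRecord

    @property
    def structure_id(self) -> str:
        return self.chain_a.rsplit("_", 1)[0]


@dataclass(frozen=True)
class AnnotationRejection:
    edge: InteractionEdge
    reason: str


def _interface_coverage(
    alignment: AlignmentRecord | None, iface: frozenset[int] | set[int]
) -> float | None:
    if alignment is None:
        return None
    c2p = alignment.chain_to_protein()
    return sum(1 for pos in iface if pos in c2p) / len(iface)


def annotate_ppi(
    edge: InteractionEdge,
    alignments: Mapping[tuple[str, str], AlignmentRecord],
    template_interfaces: Mapping[tuple[str, str], tuple[set[int], set[int]]],
) -> ChainPairAnnotation | AnnotationRejection:
    """Annotate one PPI with the best qualifying chain-pair template.

    ``template_interfaces`` maps (chain_id_1, chain_id_2) to that chain
    pair's interface residue sets.  A candidate qualifies when both chains
    have a nonempty interface and each protein covers at least 50% of its
    chain's interface residues; both protein-to-chain orientations are
    considered.  Among qualifying candidates the one maximizing
    min(coverage) wins, tie-broken by summed coverage then lexicographic
    chain pair.
    """
    candidates = []
    any_alignment = False
    for (c1, c2), (iface1, iface2) in template_interfaces.items():
        if not iface1 or not iface2:
            continue
        orientations = [(edge.protein_a, c1, iface1, edge.protein_b, c2, iface2)]
        if c1 != c2:
            orientations.append(
                (edge.protein_a, c2, iface2, edge.protein_b, c1, iface1)
            )
        for pa, ca, ia, pb, cb, ib in orientations:
            aln_a = alignments.get((pa, ca))
            aln_b = alignments.get((pb, cb))
            if aln_a is None or aln_b is None:
                continue
            any_alignment = True
            cov_a = _interface_coverage(aln_a, ia)
            cov_b = _interface_coverage(aln_b, ib)
            if cov_a >= MIN_INTERFACE_COVERAGE and cov_b >= MIN_INTERFACE_COVERAGE:
                candidates.append(
                    ChainPairAnnotation(
                        edge=edge, chain_a=ca, chain_b=cb,
                        coverage_a=cov_a, coverage_b=cov_b,
                        alignment_a=aln_a, alignment_b=aln_b,
                    )
                )
    if candidates:
        candidates.sort(
            key=lambda c: (
                -min(c.coverage_a, c.coverage_b),
                -(c.coverage_a + c.coverage_b),
                # lexicographically smallest chain pair on exact ties
                tuple(sorted((c.chain_a, c.chain_b))),
                (c.chain_a, c.chain_b),
            )
        )
        return candidates[0]
    reason = "missing-alignment" if not any_alignment else "insufficient-coverage"
    return AnnotationRejection(edge=edge, reason=reason)


@dataclass(frozen=True)
class InterfaceTransfer:
    """Template interface positions expressed in protein coordinates."""

    positions_a: frozenset[int]
    positions_b: frozenset[int]
    dropped_a: int  # template interface residues without an aligned position
    dropped_b: int


def transfer_interface(
    annotation: ChainPairAnnotation,
    chain_interfaces: tuple[set[int], set[int]],
) -> InterfaceTransfer:
    """Map chain interface positions onto each partner protein.

    Template positions without an aligned protein position are dropped and
    counted.
    """
    iface_a, iface_b = chain_interfaces
    out = []
    for aln, iface in (
        (annotation.alignment_a, iface_a),
        (annotation.alignment_b, iface_b),
    ):
        c2p = aln.chain_to_protein()
        mapped = frozenset(c2p[pos] for pos in iface if pos in c2p)
        out.append((mapped, len(iface) - len(mapped)))
    return InterfaceTransfer(
        positions_a=out[0][0], positions_b=out[1][0],
        dropped_a=out[0][1], dropped_b=out[1][1],
    )


def fixture_alignment(
    protein_id: str,
    chain_id: str,
    protein_seq: str,
    chain_seq: str,
    e_value: float = 1e-50,
) -> AlignmentRecord:
    """Locally align two sequences for fixture construction.

    Uses a substitution-matrix-scored affine-gap local alignment
    (BLOSUM62); a convenience for building test inputs, not a BLAST
    replacement (no E-value statistics — the caller supplies one).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    aln = aligner.align(protein_seq, chain_seq)[0]
    pairs = []
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        pairs.extend(
            (q + 1, s + 1) for q, s in zip(range(qs, qe), range(ss, se))
        )
    return AlignmentRecord(
        protein_id=protein_id, chain_id=chain_id,
        e_value=e_value, pairs=tuple(pairs),
    )
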