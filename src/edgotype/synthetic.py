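"""Synthetic inputs with known ground truth for the full pipeline.

Every file format the pipeline consumes can be generated here: toy chain-pair
structures with interface residues planted by construction, reference edge
lists, FASTA sequences, identity alignments, mutation tables with a
controlled flank-corruption rate, and class-conditional ddG tables whose
margins make the true edgotype unambiguous.

Toy structures use two heavy pseudo-atoms per residue (a CA-like anchor and
a CB-like offset atom) placed on a lattice: chain A lies along the x axis,
chain B along a parallel line 40 A away, and each planted interface pair is
created by moving one chain-B residue to 4.5 A below its chain-A partner.
Because the CB offset is identical for all residues, the minimum heavy-atom
distance between two residues equals the distance between their anchors, so
planted pairs sit at 4.5 A (inside the 5 A interface cutoff) and every other
cross-chain pair is beyond 6.5 A.  Scenario structures additionally append a
compact 3x3x3 residue core per chain (4.9 A spacing) so that some residues
are genuinely buried (RSA <= 0.25), giving quasi-null mutations somewhere to
live.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._tables import AA1_TO_3, STANDARD_AA
from .errors import InvalidScenarioError
from .geometry import (
    RSA_BURIAL_CUTOFF,
    interface_residues,
    parse_structure,
    residue_sasa,
    rsa,
)
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

LINE_SPACING = 10.0  # A between residue anchors along a chain
CHAIN_GAP = 40.0  # A between the two chain lines
CONTACT_DISTANCE = 4.5  # planted interface pair distance (< 5 A cutoff)
CB_OFFSET = np.array([0.0, 1.5, 0.0])
CORE_SIDE = 3  # scenario burial core is a CORE_SIDE^3 block
CORE_SPACING = 4.9

FLANK_WIDTH = 10  # residues on each side of a mutation site

MUTATION_COLUMNS = [
    "protein_id", "position", "wt_aa", "mut_aa", "source", "consequence",
    "transcript_flank", "significance", "stars", "conflicting",
    "validated", "withdrawn", "assertion", "maf", "flank_corrupted",
]


@dataclass(frozen=True)
class DdgParams:
    """Location and scale (kcal/mol) of class-conditional ddG distributions.

    Disruptive distributions are truncated from below and benign ones from
    above, keeping the true edgotype unambiguous relative to the 0.5
    (binding) and 2.0 (folding) classification thresholds.
    """

    binding_disruptive_loc: float = 2.5
    binding_disruptive_scale: float = 1.0
    binding_disruptive_min: float = 0.6
    binding_benign_loc: float = 0.0
    binding_benign_scale: float = 0.3
    binding_benign_max: float = 0.45
    folding_disruptive_loc: float = 3.5
    folding_disruptive_scale: float = 1.0
    folding_disruptive_min: float = 2.0
    folding_benign_loc: float = 0.0
    folding_benign_scale: float = 0.3
    folding_benign_max: float = 0.45


@dataclass
class SyntheticScenario:
    """Parameters of one self-contained synthetic study.

    Defaults mirror the statistical structure of the real study: the
    class-conditional edgotype probabilities are the Y2H-derived structural
    interactome fractions (97/1.5/1.5% for common non-pathogenic mutations,
    74/13/13% for pathogenic ones).
    """

    seed: int = 0
    n_proteins: int = 20
    n_ppis: int = 10
    interface_fraction: float = 0.15
    edgotype_probs_by_class: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            NONPATHOGENIC: (0.97, 0.015, 0.015),
            PATHOGENIC: (0.74, 0.13, 0.13),
        }
    )
    ddg_params: DdgParams = field(default_factory=DdgParams)
    flank_corruption_rate: float = 0.1
    n_mutations_per_class: dict[str, int] = field(
        default_factory=lambda: {NONPATHOGENIC: 120, PATHOGENIC: 60}
    )
    chain_line_length: int = 13  # residues on the lattice line per chain

    def __post_init__(self):
        if self.n_proteins <= 0 or self.n_ppis <= 0:
            raise InvalidScenarioError("counts must be positive")
        if not 0.0 < self.interface_fraction < 1.0:
            raise InvalidScenarioError("interface_fraction must be in (0, 1)")
        if not 0.0 <= self.flank_corruption_rate <= 1.0:
            raise InvalidScenarioError("flank_corruption_rate must be in [0, 1]")
        for cls, probs in self.edgotype_probs_by_class.items():
            if abs(sum(probs) - 1.0) > 1e-12:
                raise InvalidScenarioError(
                    f"edgotype probabilities for {cls!r} must sum to 1"
                )
            if min(probs) < 0:
                raise InvalidScenarioError("edgotype probabilities must be >= 0")

    @property
    def chain_length(self) -> int:
        return self.chain_line_length + CORE_SIDE**3

    @property
    def n_interface(self) -> int:
        k = max(1, round(self.interface_fraction * self.chain_length))
        if k > self.chain_line_length:
            raise InvalidScenarioError(
                "interface_fraction too large for the chain line length"
            )
        return k


# ---------------------------------------------------------------------------
# Structures


def _line_positions(n: int, z: float) -> np.ndarray:
    return np.column_stack(
        [LINE_SPACING * np.arange(n), np.zeros(n), np.full(n, z)]
    )


def _core_positions(offset: np.ndarray) -> np.ndarray:
    grid = np.arange(CORE_SIDE) * CORE_SPACING
    pts = np.array([[x, y, z] for x in grid for y in grid for z in grid])
    return pts + offset


def _write_pdb(chains: dict[str, tuple[list[str], np.ndarray]]) -> str:
    """Write chains of pseudo-residues (anchor + CB-offset atom) as PDB text.

    ``chains`` maps chain id -> (three-letter residue names, anchor coords).
    """
    st = gemmi.Structure()
    st.name = "synthetic complex"
    model = gemmi.Model("1")
    for chain_id, (names, anchors) in chains.items():
        chain = gemmi.Chain(chain_id)
        for i, (name, pos) in enumerate(zip(names, anchors), start=1):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "A"
            for atom_name, xyz in (("CA", pos), ("CB", pos + CB_OFFSET)):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


def _plant_interface(
    n_a: int,
    n_b: int,
    n_interface: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, set[int], set[int]]:
    """Anchor coordinates for two chain lines with planted contacts."""
    if n_interface < 0 or n_interface > min(n_a, n_b):
        raise InvalidScenarioError(
            f"cannot place {n_interface} interface residues on chains of "
            f"{n_a} and {n_b} residues"
        )
    pos_a = _line_positions(n_a, z=0.0)
    pos_b = _line_positions(n_b, z=CHAIN_GAP)
    idx_a = np.sort(rng.choice(n_a, size=n_interface, replace=False))
    idx_b = np.sort(rng.choice(n_b, size=n_interface, replace=False))
    for a_i, b_i in zip(idx_a, idx_b):
        pos_b[b_i] = pos_a[a_i] + np.array([0.0, 0.0, CONTACT_DISTANCE])
    iface_a = {int(i) + 1 for i in idx_a}
    iface_b = {int(i) + 1 for i in idx_b}
    return pos_a, pos_b, iface_a, iface_b


def _random_names(n: int, rng: np.random.Generator) -> list[str]:
    return [AA1_TO_3[a] for a in rng.choice(STANDARD_AA, size=n)]


def generate_toy_complex(
    n_residues_a: int,
    n_residues_b: int,
    n_interface: int,
    seed: int,
) -> tuple[str, set[int], set[int]]:
    """A two-chain PDB complex with exactly the planted interface residues.

    Returns (pdb_text, interface residues of chain A, of chain B), 1-based.
    By construction the planted cross-chain residue pairs have minimum
    heavy-atom distance 4.5 A and all other cross-chain pairs exceed 6.5 A.
    """
    if n_residues_a <= 0 or n_residues_b <= 0:
        raise InvalidScenarioError("chain sizes must be positive")
    rng = np.random.default_rng(seed)
    pos_a, pos_b, iface_a, iface_b = _plant_interface(
        n_residues_a, n_residues_b, n_interface, rng
    )
    pdb = _write_pdb(
        {
            "A": (_random_names(n_residues_a, rng), pos_a),
            "B": (_random_names(n_residues_b, rng), pos_b),
        }
    )
    return pdb, iface_a, iface_b


def _scenario_complex(
    seq_a: str,
    seq_b: str,
    n_line: int,
    n_interface: int,
    rng: np.random.Generator,
) -> tuple[str, set[int], set[int]]:
    """Line-plus-burial-core complex whose chains spell the given sequences."""
    pos_a, pos_b, iface_a, iface_b = _plant_interface(
        n_line, n_line, n_interface, rng
    )
    core_a = _core_positions(np.array([0.0, -60.0, 0.0]))
    core_b = _core_positions(np.array([0.0, 60.0, CHAIN_GAP]))
    anchors_a = np.vstack([pos_a, core_a])
    anchors_b = np.vstack([pos_b, core_b])
    names_a = [AA1_TO_3[a] for a in seq_a]
    names_b = [AA1_TO_3[a] for a in seq_b]
    pdb = _write_pdb({"A": (names_a, anchors_a), "B": (names_b, anchors_b)})
    return pdb, iface_a, iface_b


# ---------------------------------------------------------------------------
# Mutation tables


def build_flank(sequence: str, position: int, width: int = FLANK_WIDTH) -> str:
    """Flanking window: up to ``width`` residues each side of the site.

    Truncated at the sequence ends; the wild-type residue sits at the site.
    """
    if position < 1 or position > len(sequence):
        raise InvalidScenarioError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    start = max(0, position - 1 - width)
    end = min(len(sequence), position + width)
    return sequence[start:end]


def generate_mutation_table(
    protein_sequences: dict[str, str],
    n_per_class: dict[str, int],
    flank_corruption_rate: float,
    seed: int,
    positions_by_class: dict[str, list[tuple[str, int]]] | None = None,
) -> pd.DataFrame:
    """Mutation records (ClinVar-like and dbSNP-like rows in one table).

    One row per mutation; ``source`` distinguishes the pathogenic-set
    (ClinVar-like: significance/stars/conflict fields) from the common-set
    (dbSNP-like: validation/assertion/MAF fields).  A ``flank_corrupted``
    fraction of rows get one substituted residue inside the transcript
    flank, so downstream flank verification rejects exactly those rows (up
    to none when the flank window is a single residue).  Positions are
    unique across the whole table.
    """
    if not 0.0 <= flank_corruption_rate <= 1.0:
        raise InvalidScenarioError("corruption rate must be in [0, 1]")
    for pid, seq in protein_sequences.items():
        if not seq:
            raise InvalidScenarioError(f"empty sequence for {pid!r}")
    rng = np.random.default_rng(seed)
    all_positions = [
        (pid, pos)
        for pid, seq in sorted(protein_sequences.items())
        for pos in range(1, len(seq) + 1)
    ]
    n_total = sum(n_per_class.values())
    if positions_by_class is None:
        if n_total > len(all_positions):
            raise InvalidScenarioError(
                f"requested {n_total} mutations but only "
                f"{len(all_positions)} positions exist"
            )
        picks = rng.choice(len(all_positions), size=n_total, replace=False)
        chosen = [all_positions[i] for i in picks]
        positions_by_class = {}
        offset = 0
        for cls, n in n_per_class.items():
            positions_by_class[cls] = chosen[offset:offset + n]
            offset += n

    rows = []
    for cls, positions in positions_by_class.items():
        for pid, pos in positions:
            seq = protein_sequences[pid]
            wt = seq[pos - 1]
            mut = str(rng.choice([a for a in STANDARD_AA if a != wt]))
            flank = build_flank(seq, pos)
            corrupted = bool(rng.random() < flank_corruption_rate)
            if corrupted and len(flank) > 1:
                site_offset = pos - 1 - max(0, pos - 1 - FLANK_WIDTH)
                slots = [i for i in range(len(flank)) if i != site_offset]
                i = int(rng.choice(slots))
                repl = str(rng.choice([a for a in STANDARD_AA if a != flank[i]]))
                flank = flank[:i] + repl + flank[i + 1:]
            elif corrupted:
                corrupted = False  # nothing to corrupt in a 1-residue window
            is_path = cls == PATHOGENIC
            rows.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "wt_aa": wt,
                    "mut_aa": mut,
                    "source": "pathogenic-set" if is_path else "common-set",
                    "consequence": "missense",
                    "transcript_flank": flank,
                    "significance": "pathogenic" if is_path else "benign",
                    "stars": int(rng.integers(1, 5)) if is_path else 0,
                    "conflicting": False,
                    "validated": True,
                    "withdrawn": False,
                    "assertion": "" if is_path else "benign",
                    "maf": np.nan if is_path else float(rng.uniform(0.01, 0.5)),
                    "flank_corrupted": corrupted,
                }
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# ddG tables


def _trunc_draw(
    rng: np.random.Generator,
    loc: float,
    scale: float,
    low: float = -np.inf,
    high: float = np.inf,
    size: int | None = None,
):
    a = (low - loc) / scale
    b = (high - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_ddg_table(
    edgotype_truth: pd.DataFrame,
    ddg_params: DdgParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mutation folding and per-partner binding ddG records.

    ``edgotype_truth`` needs columns ``protein_id, position, wt_aa, mut_aa,
    true_edgotype, location, partners`` (semicolon-joined partner ids).
    Ground-truth edgetic mutations receive at least one binding ddG above
    the disruptive truncation, quasi-null mutations a folding ddG >= 2, and
    quasi-wild-type mutations benign values throughout.
    """
    params = ddg_params if ddg_params is not None else DdgParams()
    rng = np.random.default_rng(seed)
    rows = []
    for rec in edgotype_truth.itertuples(index=False):
        truth = rec.true_edgotype
        location = rec.location
        partners = [p for p in str(rec.partners).split(";") if p and p != "nan"]
        if truth == EDGETIC and location != INTERFACIAL:
            raise InvalidScenarioError("edgetic truth requires interfacial location")
        if truth == QUASI_NULL and location != BURIED:
            raise InvalidScenarioError("quasi-null truth requires buried location")
        key = {
            "protein_id": rec.protein_id,
            "position": rec.position,
            "wt_aa": rec.wt_aa,
            "mut_aa": rec.mut_aa,
        }
        # folding ddG: one record per mutation
        if truth == QUASI_NULL:
            fold = _trunc_draw(
                rng, params.folding_disruptive_loc, params.folding_disruptive_scale,
                low=params.folding_disruptive_min,
            )
        else:
            fold = _trunc_draw(
                rng, params.folding_benign_loc, params.folding_benign_scale,
                high=params.folding_benign_max,
            )
        rows.append({**key, "kind": "folding", "partner": "", "ddg": float(fold)})
        # binding ddG: one record per partner for interfacial mutations
        if location == INTERFACIAL:
            if truth == EDGETIC:
                if not partners:
                    raise InvalidScenarioError("edgetic mutation has no partners")
                disrupted = [p for p in partners if rng.random() < 0.5]
                if not disrupted:
                    disrupted = [partners[int(rng.integers(len(partners)))]]
            else:
                disrupted = []
            for p in partners:
                if p in disrupted:
                    ddg = _trunc_draw(
                        rng, params.binding_disruptive_loc,
                        params.binding_disruptive_scale,
                        low=params.binding_disruptive_min,
                    )
                else:
                    ddg = _trunc_draw(
                        rng, params.binding_benign_loc,
                        params.binding_benign_scale,
                        high=params.binding_benign_max,
                    )
                rows.append(
                    {**key, "kind": "binding", "partner": p, "ddg": float(ddg)}
                )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "position", "wt_aa", "mut_aa", "kind",
                 "partner", "ddg"],
    )


# ---------------------------------------------------------------------------
# Count tables


def generate_edgotype_counts(
    n_nonpath: int,
    n_path: int,
    edgotype_probs_by_class: dict[str, tuple[float, float, float]],
    seed: int,
) -> pd.DataFrame:
    """Multinomial 2x3 edgotype count table with the requested marginals."""
    rng = np.random.default_rng(seed)
    rows = {}
    for cls, n in ((NONPATHOGENIC, n_nonpath), (PATHOGENIC, n_path)):
        probs = np.asarray(edgotype_probs_by_class[cls], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise InvalidScenarioError(f"invalid probability vector for {cls!r}")
        rows[cls] = rng.multinomial(n, probs)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(EDGOTYPES))


# ---------------------------------------------------------------------------
# Full scenario


@dataclass
class ScenarioBundle:
    """All generated inputs of one scenario, plus ground truth."""

    scenario: SyntheticScenario
    outdir: Path
    paths: dict[str, Path]
    protein_sequences: dict[str, str]
    truth: pd.DataFrame  # per-mutation ground truth
    interfaces: dict[str, dict[str, set[int]]]  # template -> chain -> residues


def generate_scenario(
    scenario: SyntheticScenario, outdir: str | Path
) -> ScenarioBundle:
    """Generate and write every pipeline input for one synthetic scenario.

    Writes the edge list, protein/transcript FASTA, identity alignments,
    per-PPI template PDB files, mutation and ddG tables, the ground-truth
    label table, and a JSON sidecar echoing all parameters.  Ground-truth
    location classes are derived from the geometry module itself (interface
    membership by construction; burial from computed RSA), so end-to-end
    recovery is exact for uncorrupted records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "templates").mkdir(exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    L = scenario.chain_length

    protein_ids = [f"P{i + 1:04d}" for i in range(scenario.n_proteins)]
    sequences = {
        pid: "".join(rng.choice(STANDARD_AA, size=L)) for pid in protein_ids
    }

    # distinct unordered protein pairs
    possible = [
        (a, b)
        for i, a in enumerate(protein_ids)
        for b in protein_ids[i + 1:]
    ]
    if scenario.n_ppis > len(possible):
        raise InvalidScenarioError("more PPIs requested than protein pairs")
    picks = rng.choice(len(possible), size=scenario.n_ppis, replace=False)
    edges = sorted(possible[i] for i in picks)

    # one template complex per PPI; chains spell the protein sequences
    interfaces: dict[str, dict[str, set[int]]] = {}
    protein_iface: dict[str, dict[int, set[str]]] = {p: {} for p in protein_ids}
    protein_rsa: dict[str, dict[int, float]] = {}
    aln_rows = []
    for k, (pa, pb) in enumerate(edges):
        tid = f"T{k + 1:04d}"
        pdb, iface_a, iface_b = _scenario_complex(
            sequences[pa], sequences[pb],
            scenario.chain_line_length, scenario.n_interface, rng,
        )
        (outdir / "templates" / f"{tid}.pdb").write_text(pdb)
        interfaces[tid] = {"A": iface_a, "B": iface_b}
        for pid, chain, iface, partner in (
            (pa, "A", iface_a, pb), (pb, "B", iface_b, pa),
        ):
            for pos in iface:
                protein_iface[pid].setdefault(pos, set()).add(partner)
            chain_id = f"{tid}_{chain}"
            aln_rows.append(
                {
                    "query": pid, "subject": chain_id, "evalue": 1e-50,
                    "qstart": 1, "qend": L, "sstart": 1, "send": L,
                    "qseq": sequences[pid], "sseq": sequences[pid],
                }
            )
        # RSA from the first template containing each protein
        structure = parse_structure(pdb)
        asa = residue_sasa(structure)
        for pid, chain in ((pa, "A"), (pb, "B")):
            if pid in protein_rsa:
                continue
            residues = structure.chain(chain)
            protein_rsa[pid] = {
                r.index: rsa(asa[(chain, r.index)], r.name) for r in residues
            }

    structured = sorted(protein_rsa)  # proteins with a template

    # per-protein position pools by location class
    pools: dict[str, dict[str, list[tuple[str, int]]]] = {
        INTERFACIAL: {}, BURIED: {}, EXPOSED: {},
    }
    for pid in structured:
        for pos in range(1, L + 1):
            if pos in protein_iface[pid]:
                loc = INTERFACIAL
            elif protein_rsa[pid][pos] > RSA_BURIAL_CUTOFF:
                loc = EXPOSED
            else:
                loc = BURIED
            pools[loc].setdefault(pid, []).append((pid, pos))

    flat_pools = {
        loc: [item for pid in sorted(d) for item in d[pid]]
        for loc, d in pools.items()
    }

    # draw ground-truth edgotypes and assign compatible positions
    used: set[tuple[str, int]] = set()

    def _take(pool_names: list[str]) -> tuple[str, int] | None:
        candidates = [
            item
            for name in pool_names
            for item in flat_pools[name]
            if item not in used
        ]
        if not candidates:
            return None
        item = candidates[int(rng.integers(len(candidates)))]
        used.add(item)
        return item

    truth_rows = []
    positions_by_class: dict[str, list[tuple[str, int]]] = {}
    for cls, n in scenario.n_mutations_per_class.items():
        probs = np.asarray(scenario.edgotype_probs_by_class[cls], dtype=float)
        labels = rng.choice(list(EDGOTYPES), size=n, p=probs)
        chosen = []
        for label in labels:
            if label == EDGETIC:
                item = _take([INTERFACIAL])
                loc = INTERFACIAL
            elif label == QUASI_NULL:
                item = _take([BURIED])
                loc = BURIED
            else:
                item = _take([EXPOSED, BURIED, INTERFACIAL])
                loc = None
            if item is None:
                raise InvalidScenarioError(
                    f"not enough positions for a {label} mutation"
                )
            pid, pos = item
            if loc is None:
                if pos in protein_iface[pid]:
                    loc = INTERFACIAL
                elif protein_rsa[pid][pos] > RSA_BURIAL_CUTOFF:
                    loc = EXPOSED
                else:
                    loc = BURIED
            chosen.append(item)
            partners = sorted(protein_iface[pid].get(pos, set()))
            truth_rows.append(
                {
                    "protein_id": pid, "position": pos,
                    "phenotype_class": cls, "true_edgotype": label,
                    "location": loc, "partners": ";".join(partners),
                }
            )
        positions_by_class[cls] = chosen

    mutations = generate_mutation_table(
        sequences,
        scenario.n_mutations_per_class,
        scenario.flank_corruption_rate,
        seed=int(rng.integers(2**31)),
        positions_by_class=positions_by_class,
    )
    truth = pd.DataFrame(truth_rows).merge(
        mutations[["protein_id", "position", "wt_aa", "mut_aa",
                   "flank_corrupted"]],
        on=["protein_id", "position"],
    )
    ddg = generate_ddg_table(
        truth, scenario.ddg_params, seed=int(rng.integers(2**31))
    )

    paths = {
        "edges": outdir / "edges.tsv",
        "proteins_fasta": outdir / "proteins.fasta",
        "transcripts_fasta": outdir / "transcripts.fasta",
        "alignments": outdir / "alignments.tsv",
        "templates_dir": outdir / "templates",
        "mutations": outdir / "mutations.tsv",
        "ddg": outdir / "ddg.tsv",
        "truth": outdir / "truth.tsv",
        "sidecar": outdir / "scenario.json",
    }
    pd.DataFrame(edges, columns=["protein_a", "protein_b"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    fasta = "".join(f">{pid}\n{sequences[pid]}\n" for pid in protein_ids)
    paths["proteins_fasta"].write_text(fasta)
    paths["transcripts_fasta"].write_text(fasta)  # transcripts identical
    pd.DataFrame(aln_rows).to_csv(paths["alignments"], sep="\t", index=False)
    mutations.to_csv(paths["mutations"], sep="\t", index=False)
    ddg.to_csv(paths["ddg"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    sidecar = asdict(scenario)
    sidecar["ddg_params"] = asdict(scenario.ddg_params)
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, default=str))

    return ScenarioBundle(
        scenario=scenario,
        outdir=outdir,
        paths=paths,
        protein_sequences=sequences,
        truth=truth,
        interfaces=interfaces,
    )
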