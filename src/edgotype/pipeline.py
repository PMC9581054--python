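"""Pipeline orchestration: assembly -> geometry -> mapping -> classification
-> fitness inference, plus the worked-example report and cutoff sweeps.

Each stage reads/writes plain TSV so runs are inspectable and deterministic;
every output file is checksummed and the resolved configuration is written
beside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import classify as _classify
from . import fitness as _fitness
from . import geometry as _geometry
from . import interactome as _interactome
from . import mutations as _mutations
from .errors import MissingInputError
from .labels import (
    ASSUMPTION_I,
    ASSUMPTION_II,
    EDGETIC,
    EDGOTYPES,
    FITNESS_CLASSES,
    NONPATHOGENIC,
    PATHOGENIC,
    QUASI_NULL,
    QUASI_WILDTYPE,
)

logger = logging.getLogger(__name__)

# Printed edgotype fractions (P(T|N), P(T|M)) and count bases per dataset:
# two structural interactomes (Y2H-SI from HuRI, Lit-SI from IntAct) and the
# experimentally determined edgotypes of Sahni et al.
WORKED_EXAMPLE_FRACTIONS: dict[str, dict] = {
    "Y2H-SI": {
        "fractions": {
            QUASI_WILDTYPE: (0.97, 0.74),
            EDGETIC: (0.015, 0.13),
            QUASI_NULL: (0.015, 0.13),
        },
        "n_nonpathogenic": 1072,
        "n_pathogenic": 318,
    },
    "Lit-SI": {
        "fractions": {
            QUASI_WILDTYPE: (0.95, 0.69),
            EDGETIC: (0.02, 0.09),
            QUASI_NULL: (0.03, 0.22),
        },
        "n_nonpathogenic": 2786,
        "n_pathogenic": 1202,
    },
    "experimental": {
        "fractions": {
            QUASI_WILDTYPE: (0.92, 0.43),
            EDGETIC: (0.04, 0.31),
            QUASI_NULL: (0.04, 0.26),
        },
        "n_nonpathogenic": 47,
        "n_pathogenic": 197,
    },
}


@dataclass
class PipelineConfig:
    """Input paths, cutoffs and priors for one pipeline run."""

    edges: Path
    proteins_fasta: Path
    transcripts_fasta: Path
    alignments: Path
    templates_dir: Path
    mutations: Path
    ddg: Path
    outdir: Path
    interface_cutoff: float = _geometry.DEFAULT_INTERFACE_CUTOFF
    rsa_cutoff: float = _geometry.RSA_BURIAL_CUTOFF
    binding_cutoff: float = _classify.BINDING_DDG_CUTOFF
    folding_cutoff: float = _classify.FOLDING_DDG_CUTOFF
    priors: _fitness.FitnessPriors = field(
        default_factory=_fitness.FitnessPriors
    )
    assumption: str = ASSUMPTION_I
    seed: int = 0

    def __post_init__(self):
        for name in ("edges", "proteins_fasta", "transcripts_fasta",
                     "alignments", "templates_dir", "mutations", "ddg",
                     "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if min(self.interface_cutoff, self.rsa_cutoff,
               self.binding_cutoff, self.folding_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")

    @classmethod
    def for_scenario_dir(cls, scenario_dir: str | Path,
                         outdir: str | Path | None = None,
                         **overrides) -> "PipelineConfig":
        d = Path(scenario_dir)
        return cls(
            edges=d / "edges.tsv",
            proteins_fasta=d / "proteins.fasta",
            transcripts_fasta=d / "transcripts.fasta",
            alignments=d / "alignments.tsv",
            templates_dir=d / "templates",
            mutations=d / "mutations.tsv",
            ddg=d / "ddg.tsv",
            outdir=Path(outdir) if outdir is not None else d / "results",
            **overrides,
        )

    def to_json(self) -> str:
        cfg = dataclasses.asdict(self)
        cfg["priors"] = dataclasses.asdict(self.priors)
        return json.dumps({k: str(v) if isinstance(v, Path) else v
                           for k, v in cfg.items()}, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _require_input(path: Path, stage: str) -> None:
    if not path.exists():
        raise MissingInputError(f"stage {stage!r}: missing input {path}")


@dataclass
class ProteinGeometry:
    """Per-protein structural annotation used by classification."""

    interface_positions: dict[int, set[str]]  # position -> partner proteins
    rsa: dict[int, float]
    residue: dict[int, str]
    center_ratio: dict[int, float]
    template: str


def assemble_and_measure(
    config: PipelineConfig,
) -> tuple[list[_interactome.ChainPairAnnotation], dict[str, ProteinGeometry]]:
    """Stages 1-2: annotate PPIs with templates and measure geometry.

    Returns the accepted annotations and a per-protein geometry bundle
    (interface positions transferred to protein coordinates, RSA, residue
    types, distance-to-center ratios).  A protein appearing in several
    templates takes its RSA from the lexicographically first template.
    """
    for name in ("edges", "proteins_fasta", "alignments", "templates_dir"):
        _require_input(getattr(config, name), "assemble")
    edges = _interactome.load_interactome(config.edges)
    logger.info("assemble: %d reference edges", len(edges))
    best = _interactome.select_best_alignment(
        _interactome.read_alignments(config.alignments)
    )

    structures: dict[str, _geometry.Structure] = {}
    template_interfaces: dict[tuple[str, str], tuple[set[int], set[int]]] = {}
    for pdb_path in sorted(config.templates_dir.glob("*.pdb")):
        tid = pdb_path.stem
        structure = _geometry.parse_structure(pdb_path.read_text())
        structures[tid] = structure
        chain_ids = sorted(structure.chains)
        for i, ca in enumerate(chain_ids):
            for cb in chain_ids[i + 1:]:
                ia, ib = _geometry.interface_residues(
                    structure, ca, cb, cutoff=config.interface_cutoff
                )
                template_interfaces[(f"{tid}_{ca}", f"{tid}_{cb}")] = (ia, ib)

    annotations = []
    for edge in edges:
        result = _interactome.annotate_ppi(edge, best, template_interfaces)
        if isinstance(result, _interactome.ChainPairAnnotation):
            annotations.append(result)
        else:
            logger.info("assemble: rejected %s (%s)", edge, result.reason)
    logger.info("assemble: %d PPIs annotated with templates", len(annotations))

    geometry: dict[str, ProteinGeometry] = {}
    sasa_cache: dict[str, dict] = {}
    for ann in sorted(annotations, key=lambda a: (a.structure_id,
                                                  a.chain_a, a.chain_b)):
        tid = ann.structure_id
        structure = structures[tid]
        key = tuple(sorted((ann.chain_a, ann.chain_b)))
        iface = template_interfaces[(key[0], key[1])]
        if (key[0], key[1]) != (ann.chain_a, ann.chain_b):
            iface = (iface[1], iface[0])
        transfer = _interactome.transfer_interface(ann, iface)
        if tid not in sasa_cache:
            sasa_cache[tid] = _geometry.residue_sasa(structure)
        asa = sasa_cache[tid]
        for pid, chain_full, positions, partner in (
            (ann.edge.protein_a, ann.chain_a, transfer.positions_a,
             ann.edge.protein_b),
            (ann.edge.protein_b, ann.chain_b, transfer.positions_b,
             ann.edge.protein_a),
        ):
            chain_letter = chain_full.rsplit("_", 1)[1]
            aln = (ann.alignment_a if chain_full == ann.chain_a
                   else ann.alignment_b)
            c2p = aln.chain_to_protein()
            if pid not in geometry:
                residues = structure.chain(chain_letter)
                rsa_map, res_map, ratio_map = {}, {}, {}
                for res in residues:
                    if res.index not in c2p:
                        continue
                    ppos = c2p[res.index]
                    rsa_map[ppos] = _geometry.rsa(
                        asa[(chain_letter, res.index)], res.name
                    )
                    res_map[ppos] = res.one_letter
                    ratio_map[ppos] = _geometry.center_distance_ratio(
                        structure, chain_letter, res.index
                    )
                geometry[pid] = ProteinGeometry(
                    interface_positions={}, rsa=rsa_map, residue=res_map,
                    center_ratio=ratio_map, template=tid,
                )
            for pos in positions:
                geometry[pid].interface_positions.setdefault(pos, set()).add(
                    partner
                )
    return annotations, geometry


def classify_mutations(
    config: PipelineConfig,
    geometry: dict[str, ProteinGeometry],
    mapped: pd.DataFrame,
    binding_cutoff: float | None = None,
) -> tuple[list[_classify.EdgotypeCall], dict]:
    """Stage 4: location + edgotype call per mapped mutation.

    Mutations on proteins without structural annotation are skipped (they
    are outside the structural interactome).
    """
    _require_input(config.ddg, "classify")
    binding_cutoff = (binding_cutoff if binding_cutoff is not None
                      else config.binding_cutoff)
    ddg = _classify.group_ddg_records(_classify.parse_ddg_table(config.ddg))
    calls: list[_classify.EdgotypeCall] = []
    labels: dict[_classify.MutationKey, str] = {}
    skipped = 0
    for row in mapped.itertuples(index=False):
        pid = row.protein_id
        if pid not in geometry:
            skipped += 1
            continue
        geo = geometry[pid]
        pos = int(row.position)
        key = (pid, pos, row.wt_aa, row.mut_aa)
        location = _classify.classify_location(
            pos, set(geo.interface_positions), geo.rsa.get(pos),
            rsa_cutoff=config.rsa_cutoff,
        )
        slot = ddg.get(key, {"binding": [], "folding": None})
        call = _classify.classify_edgotype(
            key, location,
            binding_records=slot["binding"],
            folding_record=slot["folding"],
            binding_cutoff=binding_cutoff,
            folding_cutoff=config.folding_cutoff,
            rsa_value=geo.rsa.get(pos),
        )
        calls.append(call)
        labels[key] = (PATHOGENIC if row.source == "pathogenic-set"
                       else NONPATHOGENIC)
    logger.info("classify: %d calls, %d outside structural interactome",
                len(calls), skipped)
    return calls, labels


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write per-stage TSV outputs.

    Returns a result bundle with the annotations, geometry, mapped
    mutations, edgotype calls, count table, posteriors and merged summary.
    Deterministic given the inputs and configuration.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    annotations, geometry = assemble_and_measure(config)
    pd.DataFrame(
        [
            {
                "protein_a": a.edge.protein_a, "protein_b": a.edge.protein_b,
                "chain_a": a.chain_a, "chain_b": a.chain_b,
                "coverage_a": a.coverage_a, "coverage_b": a.coverage_b,
            }
            for a in annotations
        ]
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)

    geo_rows = []
    for pid in sorted(geometry):
        geo = geometry[pid]
        for pos in sorted(geo.rsa):
            geo_rows.append(
                {
                    "protein_id": pid, "position": pos,
                    "residue": geo.residue[pos],
                    "rsa": geo.rsa[pos],
                    "center_distance_ratio": geo.center_ratio[pos],
                    "interfacial_partners": ";".join(
                        sorted(geo.interface_positions.get(pos, set()))
                    ),
                }
            )
    pd.DataFrame(geo_rows).to_csv(out / "geometry.tsv", sep="\t", index=False)

    # stage 3: mutation mapping
    for name in ("mutations", "transcripts_fasta", "proteins_fasta"):
        _require_input(getattr(config, name), "map")
    table = pd.read_csv(config.mutations, sep="\t")
    transcripts = _read_fasta(config.transcripts_fasta)
    proteins = _read_fasta(config.proteins_fasta)
    rejection_log: dict[str, dict[str, int]] = {}

    path_rows = table[table["source"] == "pathogenic-set"]
    common_rows = table[table["source"] == "common-set"]
    f_path = _mutations.filter_clinvar(path_rows)
    f_common = _mutations.filter_dbsnp(common_rows)
    rejection_log["filter_clinvar"] = f_path.rejections
    rejection_log["filter_dbsnp"] = f_common.rejections
    m_path = _mutations.map_mutations(f_path.records, transcripts, proteins)
    m_common = _mutations.map_mutations(f_common.records, transcripts, proteins)
    rejection_log["verify_flank_pathogenic"] = m_path.rejections
    rejection_log["verify_flank_common"] = m_common.rejections
    d_path = _mutations.dedupe_positions(m_path.records)
    d_common = _mutations.dedupe_positions(m_common.records)
    rejection_log["dedupe"] = {
        "pathogenic": d_path.rejections["duplicate-position"],
        "common": d_common.rejections["duplicate-position"],
    }
    x_common = _mutations.exclude_overlap(d_common.records, d_path.records)
    rejection_log["exclude_overlap"] = x_common.rejections
    mapped = pd.concat([d_path.records, x_common.records], ignore_index=True)
    mapped.to_csv(out / "mapped_mutations.tsv", sep="\t", index=False)
    (out / "rejections.json").write_text(json.dumps(rejection_log, indent=2))
    logger.info("map: %d pathogenic + %d common mutations mapped",
                len(d_path.records), len(x_common.records))

    calls, labels = classify_mutations(config, geometry, mapped)
    pd.DataFrame(
        [
            {
                "protein_id": c.key[0], "position": c.key[1],
                "wt_aa": c.key[2], "mut_aa": c.key[3],
                "phenotype_class": labels[c.key],
                "location": c.location, "edgotype": c.edgotype,
                "disrupted_partners": ";".join(c.disrupted_partners),
                "rsa": c.rsa, "folding_ddg": c.folding_ddg,
            }
            for c in calls
        ]
    ).to_csv(out / "edgotype_calls.tsv", sep="\t", index=False)
    counts, fractions = _classify.edgotype_counts(calls, labels)
    counts.to_csv(out / "edgotype_counts.tsv", sep="\t")
    fractions.to_csv(out / "edgotype_fractions.tsv", sep="\t")

    # stage 5: fitness inference under both assumptions
    posteriors = {}
    ci = {}
    for assumption in (ASSUMPTION_I, ASSUMPTION_II):
        cond = _fitness.conditional_probs(counts, assumption)
        posteriors[assumption] = _fitness.fitness_posterior(cond, config.priors)
        ci[assumption] = _fitness.bland_ci(cond, config.priors)
    post_rows = []
    for assumption, posts in posteriors.items():
        for t, post in posts.items():
            for f in FITNESS_CLASSES:
                lo, hi = ci[assumption][t][f]
                post_rows.append(
                    {
                        "assumption": assumption, "edgotype": t,
                        "fitness_class": f, "estimate": post.posteriors[f],
                        "ci95_low": lo, "ci95_high": hi,
                    }
                )
    posterior_df = pd.DataFrame(post_rows)
    posterior_df.to_csv(out / "posteriors.tsv", sep="\t", index=False)
    merged = _fitness.merge_assumptions(
        posteriors[ASSUMPTION_I], posteriors[ASSUMPTION_II]
    )
    merged.to_csv(out / "merged_posteriors.tsv", sep="\t", index=False)

    checksums = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2))

    return {
        "annotations": annotations,
        "geometry": geometry,
        "mapped": mapped,
        "calls": calls,
        "labels": labels,
        "counts": counts,
        "fractions": fractions,
        "posteriors": posterior_df,
        "merged": merged,
        "outdir": out,
    }


def worked_example_report(
    priors: _fitness.FitnessPriors | None = None,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Fitness posteriors for the three published edgotype datasets.

    Pure arithmetic from the printed conditional edgotype fractions and the
    fitness-class priors, under both assumptions, with Bland/delta 95%
    intervals and the merged (Assumption I vs average) summary ranges.
    """
    priors = priors if priors is not None else _fitness.DEFAULT_PRIORS
    rows = []
    for dataset, spec in WORKED_EXAMPLE_FRACTIONS.items():
        posts = {}
        cis = {}
        for assumption in (ASSUMPTION_I, ASSUMPTION_II):
            cond = _fitness.conditional_probs_from_fractions(
                spec["fractions"],
                n_nonpathogenic=spec["n_nonpathogenic"],
                n_pathogenic=spec["n_pathogenic"],
                assumption=assumption,
            )
            posts[assumption] = _fitness.fitness_posterior(cond, priors)
            cis[assumption] = (_fitness.bland_ci(cond, priors)
                               if with_ci else None)
        merged = _fitness.merge_assumptions(
            posts[ASSUMPTION_I], posts[ASSUMPTION_II]
        ).set_index(["edgotype", "fitness_class"])
        for assumption in (ASSUMPTION_I, ASSUMPTION_II):
            for t in EDGOTYPES:
                post = posts[assumption][t]
                for f in FITNESS_CLASSES:
                    row = {
                        "dataset": dataset, "assumption": assumption,
                        "edgotype": t, "fitness_class": f,
                        "p_t": post.p_t, "estimate": post.posteriors[f],
                        "merged_low": merged.loc[(t, f), "merged_low"],
                        "merged_high": merged.loc[(t, f), "merged_high"],
                    }
                    if with_ci:
                        lo, hi = cis[assumption][t][f]
                        row["ci95_low"], row["ci95_high"] = lo, hi
                    rows.append(row)
    return pd.DataFrame(rows)


INTERFACE_SWEEP_CUTOFFS = (4.0, 5.0, 6.0)
BINDING_SWEEP_CUTOFFS = (0.3, 0.5, 0.7)


def cutoff_sweep(
    config: PipelineConfig,
    interface_cutoffs=INTERFACE_SWEEP_CUTOFFS,
    binding_cutoffs=BINDING_SWEEP_CUTOFFS,
) -> pd.DataFrame:
    """Robustness sweep over interface-distance and binding-ddG cutoffs.

    Re-runs classification at each cutoff combination and reports the ratio
    diagnostics P(E|N)/P(E|M) and P(QW|N)/P(QW|M) that the fitness
    posteriors for edgetic and quasi-wild-type mutations depend on.
    """
    table = pd.read_csv(config.mutations, sep="\t")
    transcripts = _read_fasta(config.transcripts_fasta)
    proteins = _read_fasta(config.proteins_fasta)
    f_path = _mutations.filter_clinvar(table[table["source"] == "pathogenic-set"])
    f_common = _mutations.filter_dbsnp(table[table["source"] == "common-set"])
    mapped = pd.concat(
        [
            _mutations.map_mutations(f_path.records, transcripts,
                                     proteins).records,
            _mutations.map_mutations(f_common.records, transcripts,
                                     proteins).records,
        ],
        ignore_index=True,
    )
    rows = []
    for d in interface_cutoffs:
        cfg = dataclasses.replace(config, interface_cutoff=float(d))
        _, geometry = assemble_and_measure(cfg)
        for b in binding_cutoffs:
            calls, labels = classify_mutations(
                cfg, geometry, mapped, binding_cutoff=float(b)
            )
            _, fractions = _classify.edgotype_counts(calls, labels)
            rows.append(
                {
                    "interface_cutoff": d,
                    "binding_cutoff": b,
                    "p_e_given_n": fractions.loc[NONPATHOGENIC, EDGETIC],
                    "p_e_given_m": fractions.loc[PATHOGENIC, EDGETIC],
                    "p_qw_given_n": fractions.loc[NONPATHOGENIC,
                                                  QUASI_WILDTYPE],
                    "p_qw_given_m": fractions.loc[PATHOGENIC, QUASI_WILDTYPE],
                    "edgetic_ratio": (
                        fractions.loc[NONPATHOGENIC, EDGETIC]
                        / fractions.loc[PATHOGENIC, EDGETIC]
                        if fractions.loc[PATHOGENIC, EDGETIC] > 0 else float("nan")
                    ),
                    "qw_ratio": (
                        fractions.loc[NONPATHOGENIC, QUASI_WILDTYPE]
                        / fractions.loc[PATHOGENIC, QUASI_WILDTYPE]
                        if fractions.loc[PATHOGENIC, QUASI_WILDTYPE] > 0
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
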