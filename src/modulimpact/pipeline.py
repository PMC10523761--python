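"""End-to-end orchestration of the module-impact analysis.

Stages run in a fixed order: gene-set derivation, network construction
and tissue filtering, term enrichment with randomization FDR, module
library extraction, impact scoring and selection, super-module
coalescing, and the association statistics.  Every stage is pure given
its inputs and the seed, so a config maps to byte-identical outputs.

The analysis can be driven fully in memory (:func:`run_analysis`, or
:func:`run_on_bundle` for a synthetic benchmark) or from files via a
single YAML config (:func:`run_pipeline`), which writes all result
tables and a parameter log to an output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from . import io_tables
from .assoc_stats import (
    Chi2Result,
    IntersectionTest,
    WilcoxonResult,
    compare_selected_vs_rest,
    multiset_intersection_p,
    rip_prevalence,
)
from .enrichment import EnrichmentResult, enrich_terms, randomization_fdr
from .gene_sets import (
    KnockdownProfile,
    RipProfile,
    call_bound,
    neuronal_universe,
    profile_from_tables,
)
from .impact import ImpactReport, compute_impact_report, select_modules
from .io_tables import format_float, write_tsv
from .module_library import ModuleLibrary, build_library
from .network_builder import (
    NetworkSummary,
    build_network,
    filter_by_universe,
    network_summary,
)
from .supermodules import (
    SuperModule,
    build_overlap_graph,
    coalesce,
    supermodule_overlap,
)
from .synthetic_data import BenchmarkBundle

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "StageError",
    "run_analysis",
    "run_on_bundle",
    "run_pipeline",
    "write_outputs",
    "extract_altered_subnetwork",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineParams:
    """All tunable thresholds, with the analysis defaults."""

    fpkm_threshold: float = 1.0
    de_alpha: float = 0.05
    as_alpha: float = 0.05
    rip_alpha: float = 0.05
    n_rand: int = 1000
    fdr_threshold: float = 0.1
    seed: int = 0
    min_module_size: int = 10
    max_module_size: int = 100
    largest_component_fraction: float = 0.9
    impact_threshold: float = 20.0
    min_jaccard: float = 0.2

    def __post_init__(self):
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")
        for name in ("de_alpha", "as_alpha", "rip_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if self.min_module_size > self.max_module_size:
            raise ValueError("min_module_size must not exceed max_module_size")


@dataclass(frozen=True)
class PipelineResult:
    params: PipelineParams
    universe: frozenset[str]
    unspecific_summary: NetworkSummary
    tissue_summary: NetworkSummary
    tissue_net: nx.Graph
    profiles: tuple[KnockdownProfile, ...]
    rip_profiles: tuple[RipProfile, ...]
    enrichment: tuple[EnrichmentResult, ...]
    library: ModuleLibrary
    impact_report: ImpactReport
    selected_ids: frozenset[str]
    supermodules: tuple[SuperModule, ...]
    #: Wilcoxon on disease-linked percentages, selected vs rest (None if
    #: one group is empty), plus the two groups of per-module fractions
    disease_test: WilcoxonResult | None
    disease_fractions: tuple[tuple[float, ...], tuple[float, ...]]
    #: RIP prevalence per gene group + pairwise chi-square results
    rip_fractions: Mapping[str, float | None]
    rip_tests: tuple[tuple[str, str, Chi2Result], ...]
    #: three-condition overlap tests for DE-up / DE-down / AS gene sets
    intersection_tests: Mapping[str, IntersectionTest]


def run_analysis(
    edge_list: Sequence[tuple[str, str]],
    expression: Mapping[str, float],
    annotations: Sequence[tuple[str, str, str]],
    dea: Mapping[str, Mapping[str, tuple[float, float | None]]],
    splicing: Mapping[str, Mapping[str, float]],
    rip: Mapping[tuple[str, str], Mapping[str, tuple[float, float | None]]],
    disease: Mapping[str, bool],
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run the full analysis on in-memory tables."""

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("gene_sets"):
        universe = neuronal_universe(expression, params.fpkm_threshold)
        profiles = tuple(
            profile_from_tables(
                condition,
                dea[condition],
                splicing.get(condition, {}),
                universe=universe,
                de_alpha=params.de_alpha,
                as_alpha=params.as_alpha,
            )
            for condition in sorted(dea)
        )
        rip_profiles = tuple(
            RipProfile(
                protein=protein,
                compartment=compartment,
                bound=call_bound(table, params.rip_alpha) & universe,
            )
            for (protein, compartment), table in sorted(rip.items())
        )

    with stage("network_builder"):
        unspecific = build_network(edge_list)
        tissue = filter_by_universe(unspecific, universe)

    with stage("enrichment"):
        results = enrich_terms(set(tissue.nodes), set(unspecific.nodes), annotations)
        results = randomization_fdr(
            results,
            candidate_size=tissue.number_of_nodes(),
            background=set(unspecific.nodes),
            annotations=annotations,
            n_rand=params.n_rand,
            seed=params.seed,
            fdr_threshold=params.fdr_threshold,
        )

    with stage("module_library"):
        library = build_library(
            results,
            annotations,
            tissue,
            min_size=params.min_module_size,
            max_size=params.max_module_size,
            largest_component_fraction=params.largest_component_fraction,
        )

    with stage("impact"):
        report = compute_impact_report(
            library, profiles, threshold=params.impact_threshold,
            rip_profiles=rip_profiles,
        )
        selected_ids = select_modules(report)

    with stage("supermodules"):
        selected_modules = [m for m in library if m.term_id in selected_ids]
        if selected_modules:
            overlap_graph = build_overlap_graph(selected_modules, profiles)
            supers = coalesce(overlap_graph, min_jaccard=params.min_jaccard)
        else:
            supers = ()

    with stage("assoc_stats"):
        disease_test = None
        frac_selected: tuple[float, ...] = ()
        frac_rest: tuple[float, ...] = ()
        if selected_ids and len(selected_ids) < len(library):
            disease_test, xs, ys = compare_selected_vs_rest(
                library, selected_ids, disease
            )
            frac_selected, frac_rest = tuple(xs), tuple(ys)

        bound_any = frozenset().union(*(r.bound for r in rip_profiles)) if rip_profiles else frozenset()
        altered_any = frozenset().union(*(p.altered for p in profiles)) if profiles else frozenset()
        in_selected = frozenset().union(
            *(m.nodes for m in library if m.term_id in selected_ids)
        ) if selected_ids else frozenset()
        in_library = frozenset().union(*(m.nodes for m in library)) if len(library) else frozenset()
        groups = {
            "selected_modules": altered_any & in_selected,
            "non_selected_modules": altered_any & (in_library - in_selected),
            "no_module": altered_any - in_library,
        }
        rip_fracs, rip_tests = _safe_rip_prevalence(groups, bound_any)

        intersections: dict[str, IntersectionTest] = {}
        n_universe = len(universe)
        for kind in ("de_up", "de_down", "as_set"):
            sets = [getattr(p, kind) for p in profiles]
            if len(sets) >= 2 and all(sets) and n_universe > 0:
                observed = len(frozenset.intersection(*sets))
                intersections[kind] = multiset_intersection_p(
                    n_universe, [len(s) for s in sets], observed
                )

    return PipelineResult(
        params=params,
        universe=universe,
        unspecific_summary=network_summary(unspecific),
        tissue_summary=network_summary(tissue),
        tissue_net=tissue,
        profiles=profiles,
        rip_profiles=rip_profiles,
        enrichment=tuple(results),
        library=library,
        impact_report=report,
        selected_ids=selected_ids,
        supermodules=supers,
        disease_test=disease_test,
        disease_fractions=(frac_selected, frac_rest),
        rip_fractions=rip_fracs,
        rip_tests=tuple(rip_tests),
        intersection_tests=intersections,
    )


def _safe_rip_prevalence(groups, bound_any):
    fracs, tests = rip_prevalence(groups, bound_any)
    safe_tests = []
    for a, b, res in tests:
        safe_tests.append((a, b, res))
    return fracs, safe_tests


def run_on_bundle(
    bundle: BenchmarkBundle, params: PipelineParams = PipelineParams()
) -> PipelineResult:
    """Run the analysis on a synthetic benchmark bundle."""
    return run_analysis(
        edge_list=bundle.edge_list,
        expression=bundle.expression,
        annotations=bundle.annotations,
        dea=bundle.dea,
        splicing=bundle.splicing,
        rip=bundle.rip,
        disease=bundle.disease,
        params=params,
    )


# ---------------------------------------------------------------------------
# file-driven entry point


def run_pipeline(config: Mapping, out_dir) -> PipelineResult:
    """Run the analysis from a config mapping (paths + parameters).

    Expected config keys: ``inputs`` (edges, expression, annotations,
    dea: {condition: path}, splicing: {condition: path-or-list},
    rip: {"protein/compartment": path}, disease) and optional ``params``
    overriding any :class:`PipelineParams` field.  All result tables are
    written to ``out_dir``.
    """
    inputs = config["inputs"]
    params = PipelineParams(**config.get("params", {}))

    edge_list = io_tables.read_edge_list(inputs["edges"])
    expression = io_tables.read_table(inputs["expression"], "expression")
    annotations = io_tables.read_table(inputs["annotations"], "annotation")
    dea = {
        cond: io_tables.read_table(path, "dea")
        for cond, path in inputs["dea"].items()
    }
    splicing = {}
    for cond, path in inputs.get("splicing", {}).items():
        paths = path if isinstance(path, (list, tuple)) else [path]
        merged: dict[str, float] = {}
        for p in paths:
            for gene, fdr in io_tables.read_table(p, "splicing").items():
                merged[gene] = min(fdr, merged.get(gene, 1.0))
        splicing[cond] = merged
    rip = {}
    for key, path in inputs.get("rip", {}).items():
        protein, _, compartment = key.partition("/")
        rip[(protein, compartment or "cytoplasmic")] = io_tables.read_table(path, "dea")
    disease = (
        io_tables.read_table(inputs["disease"], "disease")
        if "disease" in inputs
        else {}
    )

    result = run_analysis(
        edge_list, expression, annotations, dea, splicing, rip, disease, params
    )
    write_outputs(result, out_dir, disease=disease)
    return result


# ---------------------------------------------------------------------------
# writers


def _fmt_bool(x: bool) -> str:
    return "1" if x else "0"


def write_outputs(result: PipelineResult, out_dir, disease: Mapping[str, bool] | None = None) -> None:
    """Write every result table plus a parameter log, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = [p.condition for p in result.profiles]

    write_tsv(
        out / "network_summary.tsv",
        ("network", "n_nodes", "n_edges", "n_components", "mean_degree", "max_degree"),
        [
            (label, str(s.n_nodes), str(s.n_edges), str(s.n_components),
             format_float(s.mean_degree), str(s.max_degree))
            for label, s in (
                ("unspecific", result.unspecific_summary),
                ("tissue", result.tissue_summary),
            )
        ],
    )

    write_tsv(
        out / "enrichment.tsv",
        ("term_id", "term_name", "k", "K", "n", "N", "p", "fdr", "enriched"),
        [
            (r.term_id, r.term_name, str(r.k), str(r.K), str(r.n), str(r.N),
             format_float(r.p), format_float(r.fdr), _fmt_bool(bool(r.enriched)))
            for r in sorted(result.enrichment, key=lambda r: r.term_id)
        ],
    )

    write_tsv(
        out / "modules.tsv",
        ("term_id", "term_name", "size", "n_components", "nodes"),
        [
            (m.term_id, m.term_name, str(m.size), str(len(m.components)),
             ",".join(sorted(m.nodes)))
            for m in result.library
        ],
    )

    impact_header = ["term_id"] + [f"impact_{c}" for c in conditions] + [
        "overall_impact", "selected",
    ]
    write_tsv(
        out / "impact.tsv",
        impact_header,
        [
            tuple(
                [mi.term_id]
                + [format_float(mi.impact[c]) for c in conditions]
                + [format_float(mi.overall_impact), _fmt_bool(mi.selected)]
            )
            for mi in sorted(result.impact_report, key=lambda m: m.term_id)
        ],
    )

    anno_header = (
        ["term_id", "gene"]
        + [f"de_{c}" for c in conditions]
        + [f"as_{c}" for c in conditions]
        + ["bound_by", "disease"]
    )
    anno_rows = []
    disease = disease or {}
    for mi in sorted(result.impact_report, key=lambda m: m.term_id):
        for node in mi.node_annotations:
            anno_rows.append(
                tuple(
                    [mi.term_id, node.gene]
                    + [node.de_state[c] for c in conditions]
                    + [_fmt_bool(node.as_flag[c]) for c in conditions]
                    + [",".join(node.bound_by) or "-",
                       _fmt_bool(disease.get(node.gene, False))]
                )
            )
    write_tsv(out / "node_annotations.tsv", anno_header, anno_rows)

    impact_by_id = result.impact_report.by_id()
    sm_header = ["supermodule_id", "members", "n_modules", "n_nodes"] + [
        f"mean_impact_{c}" for c in conditions
    ]
    sm_rows = []
    for sm in result.supermodules:
        means = [
            sum(impact_by_id[m].impact[c] for m in sm.member_modules)
            / len(sm.member_modules)
            for c in conditions
        ]
        sm_rows.append(
            tuple(
                [sm.id, ",".join(sorted(sm.member_modules)),
                 str(len(sm.member_modules)), str(sm.size)]
                + [format_float(v) for v in means]
            )
        )
    write_tsv(out / "supermodules.tsv", sm_header, sm_rows)

    overlap_rows = []
    for i, a in enumerate(result.supermodules):
        for b in result.supermodules[i + 1 :]:
            overlap_rows.append((a.id, b.id, format_float(supermodule_overlap(a, b))))
    write_tsv(out / "supermodule_overlap.tsv",
              ("supermodule_a", "supermodule_b", "overlap_pct"), overlap_rows)

    stats_rows = []
    if result.disease_test is not None:
        stats_rows.append(
            ("wilcoxon_disease", "selected_vs_rest",
             format_float(result.disease_test.statistic),
             format_float(result.disease_test.p))
        )
    else:
        stats_rows.append(("wilcoxon_disease", "selected_vs_rest", "NA", "NA"))
    for a, b, res in result.rip_tests:
        stats_rows.append(
            (f"chi2_rip_{a}_vs_{b}", f"{a}|{b}",
             format_float(res.chi2), format_float(res.p))
        )
    for name in sorted(result.rip_fractions):
        frac = result.rip_fractions[name]
        stats_rows.append(
            (f"rip_fraction_{name}", name,
             format_float(frac) if frac is not None else "NA", "NA")
        )
    write_tsv(out / "stats.tsv", ("test", "groups", "statistic", "p"), stats_rows)

    inter_rows = []
    for kind in sorted(result.intersection_tests):
        t = result.intersection_tests[kind]
        inter_rows.append(
            (kind, "x".join(str(s) for s in t.set_sizes), str(t.universe_size),
             str(t.observed), format_float(t.expected), format_float(t.fold),
             format_float(t.p_upper))
        )
    write_tsv(
        out / "intersections.tsv",
        ("gene_set", "set_sizes", "universe", "observed", "expected", "fold", "p_upper"),
        inter_rows,
    )

    log_lines = ["[params]"]
    for f in dataclasses.fields(result.params):
        log_lines.append(f"{f.name} = {getattr(result.params, f.name)}")
    log_lines += [
        "",
        "[stages]",
        f"universe_size = {len(result.universe)}",
        f"unspecific_nodes = {result.unspecific_summary.n_nodes}",
        f"unspecific_edges = {result.unspecific_summary.n_edges}",
        f"tissue_nodes = {result.tissue_summary.n_nodes}",
        f"tissue_edges = {result.tissue_summary.n_edges}",
        f"terms_tested = {len(result.enrichment)}",
        f"terms_enriched = {sum(1 for r in result.enrichment if r.enriched)}",
        f"library_modules = {len(result.library)}",
        f"selected_modules = {len(result.selected_ids)}",
        f"supermodules = {len(result.supermodules)}",
    ]
    (out / "log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# focused subnetwork extraction


def extract_altered_subnetwork(
    supermodule: SuperModule,
    net: nx.Graph,
    profiles: Sequence[KnockdownProfile],
    rip_profiles: Sequence[RipProfile] = (),
    disease: Mapping[str, bool] | None = None,
) -> tuple[list[dict], list[tuple[str, str]]]:
    """Induced subnetwork of a super-module's altered nodes.

    Nodes altered in at least one condition are induced on the tissue
    network; nodes without a direct interaction to another altered node
    are dropped.  Each kept node is annotated with the number of
    conditions in which it is altered, its DE direction and AS flag per
    condition, whether it is bound in any RIP pull-down, and its
    disease-link flag.
    """
    disease = disease or {}
    altered_any = frozenset().union(*(p.altered for p in profiles)) if profiles else frozenset()
    candidates = supermodule.nodes & altered_any & set(net.nodes)
    sub = net.subgraph(candidates)
    kept = {n for n in sub.nodes if sub.degree(n) > 0}
    bound_any = frozenset().union(*(r.bound for r in rip_profiles)) if rip_profiles else frozenset()

    nodes = []
    for gene in sorted(kept):
        de_state = {}
        as_flag = {}
        n_altered = 0
        for p in profiles:
            state = "up" if gene in p.de_up else ("down" if gene in p.de_down else "-")
            de_state[p.condition] = state
            as_flag[p.condition] = gene in p.as_set
            if state != "-" or as_flag[p.condition]:
                n_altered += 1
        nodes.append(
            {
                "gene": gene,
                "n_conditions_altered": n_altered,
                "de_state": de_state,
                "as_flag": as_flag,
                "bound": gene in bound_any,
                "disease": disease.get(gene, False),
            }
        )
    edges = sorted(tuple(sorted(e)) for e in sub.subgraph(kept).edges)
    return nodes, edges
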