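"""Per-module knockdown impact scoring and module selection.

The impact of a knockdown on a module is the percentage of module nodes
whose transcript is altered (DE in either direction, or AS) in that
condition.  The *overall impact* of a module is the impact of the
knockdown affecting it least, i.e. the minimum over conditions; a
module with overall impact of X% therefore has at least X% of its nodes
altered by every knockdown.  Modules are selected when their overall
impact reaches an inclusive threshold (default 20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .gene_sets import KnockdownProfile, RipProfile
from .module_library import FunctionalModule, ModuleLibrary

__all__ = [
    "NodeAnnotation",
    "ModuleImpact",
    "ImpactReport",
    "module_impact",
    "overall_impact",
    "compute_impact_report",
    "select_modules",
]


@dataclass(frozen=True)
class NodeAnnotation:
    gene: str
    de_state: Mapping[str, str]  # condition -> "up" | "down" | "-"
    as_flag: Mapping[str, bool]  # condition -> altered splicing
    bound_by: tuple[str, ...]  # proteins binding this transcript (any compartment)

    @property
    def n_conditions_altered(self) -> int:
        return sum(
            1
            for c in self.de_state
            if self.de_state[c] != "-" or self.as_flag.get(c, False)
        )


@dataclass(frozen=True)
class ModuleImpact:
    term_id: str
    impact: Mapping[str, float]  # condition -> percentage
    overall_impact: float
    selected: bool
    node_annotations: tuple[NodeAnnotation, ...]


@dataclass(frozen=True)
class ImpactReport:
    modules: tuple[ModuleImpact, ...]
    threshold: float

    def __iter__(self):
        return iter(self.modules)

    def by_id(self) -> dict[str, ModuleImpact]:
        return {m.term_id: m for m in self.modules}


def module_impact(module: FunctionalModule, profile: KnockdownProfile) -> float:
    """Percentage of module nodes altered in one condition."""
    if module.size == 0:
        raise ValueError(f"module {module.term_id} is empty")
    return 100.0 * len(module.nodes & profile.altered) / module.size


def overall_impact(impacts: Mapping[str, float]) -> float:
    """Impact in the least-affected condition (the minimum)."""
    if not impacts:
        raise ValueError("at least one condition required")
    return min(impacts.values())


def _annotate_node(
    gene: str,
    profiles: Sequence[KnockdownProfile],
    rip_profiles: Sequence[RipProfile],
) -> NodeAnnotation:
    de_state = {}
    as_flag = {}
    for p in profiles:
        if gene in p.de_up:
            de_state[p.condition] = "up"
        elif gene in p.de_down:
            de_state[p.condition] = "down"
        else:
            de_state[p.condition] = "-"
        as_flag[p.condition] = gene in p.as_set
    bound_by = tuple(sorted({r.protein for r in rip_profiles if gene in r.bound}))
    return NodeAnnotation(gene=gene, de_state=de_state, as_flag=as_flag, bound_by=bound_by)


def compute_impact_report(
    library: ModuleLibrary | Sequence[FunctionalModule],
    profiles: Sequence[KnockdownProfile],
    threshold: float = 20.0,
    rip_profiles: Sequence[RipProfile] = (),
) -> ImpactReport:
    """Score every library module against every knockdown profile."""
    if not profiles:
        raise ValueError("at least one knockdown profile required")
    out = []
    for module in library:
        impacts = {p.condition: module_impact(module, p) for p in profiles}
        overall = overall_impact(impacts)
        annotations = tuple(
            _annotate_node(g, profiles, rip_profiles) for g in sorted(module.nodes)
        )
        out.append(
            ModuleImpact(
                term_id=module.term_id,
                impact=impacts,
                overall_impact=overall,
                selected=overall >= threshold,
                node_annotations=annotations,
            )
        )
    return ImpactReport(modules=tuple(out), threshold=threshold)


def select_modules(report: ImpactReport, threshold: float | None = None) -> frozenset[str]:
    """Module ids whose overall impact meets the (inclusive) threshold."""
    thr = report.threshold if threshold is None else threshold
    return frozenset(m.term_id for m in report if m.overall_impact >= thr)
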