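"""Meta-QTL synthesis by maximal cliques of an interval-overlap graph.

Primary QTL within a trait group are nodes of an undirected graph with an
edge whenever two QTL sit on the same linkage group and their closed
1.5-LOD support intervals intersect (touching endpoints count). Each
maximal clique of that graph is a meta-QTL. Because intervals on a line
have the Helly property — pairwise-intersecting intervals share a common
point — every clique has a non-empty common intersection, so the meta-QTL
extents (max of member left extents, min of member right extents) always
satisfy lo <= hi, and the synthetic position is their midpoint.

Filters follow the standard reporting rules: "stable" within-trait meta-QTL
must span at least three of the four year models and have mean marker R²
of at least 10%; group-level filter sets (minimum population / study /
trait / model counts, mean R²) are AND-combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import operator

import networkx as nx

from cranqtl.qtl import QtlHit

_COMPARATORS = {">=": operator.ge, ">": operator.gt, "<=": operator.le,
                "<": operator.lt, "==": operator.eq}

_FILTER_STATS = ("mean_marker_r2", "n_models", "n_traits",
                 "n_populations", "n_studies", "n_methods")


@dataclass
class TraitGroup:
    """A synonym set of traits analyzed together, with its AND-combined filters."""

    group_id: str
    traits: list[str]
    populations: list[str] = field(default_factory=list)
    studies: list[str] = field(default_factory=list)
    filters: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("trait group needs at least one trait")
        for stat, cmp, _ in self.filters:
            if stat not in _FILTER_STATS:
                raise ValueError(f"unknown filter statistic {stat!r}; "
                                 f"expected one of {_FILTER_STATS}")
            if cmp not in _COMPARATORS:
                raise ValueError(f"unknown comparator {cmp!r}")

    def select(self, hits: list[QtlHit]) -> list[QtlHit]:
        """Hits whose trait (and population/study scope, if set) match the group."""
        out = []
        for h in hits:
            if h.trait not in self.traits:
                continue
            if self.populations and h.population not in self.populations:
                continue
            if self.studies and h.study not in self.studies:
                continue
            out.append(h)
        return out


def round_report(x: float, decimals: int = 1) -> float:
    """Half-away-from-zero rounding used for reported cM positions."""
    f = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


@dataclass
class MetaQtl:
    """A maximal clique of overlapping primary QTL, with synthesized summary."""

    linkage_group: int
    lo: float
    hi: float
    position: float                 # exact midpoint (lo+hi)/2, full precision
    members: list[QtlHit]
    mean_marker_r2: float
    mean_effect_maternal: float
    mean_effect_paternal: float
    mean_effect_interaction: float
    traits: list[str]
    populations: list[str]
    studies: list[str]
    models: list[str]
    methods: list[str]

    @property
    def position_report(self) -> float:
        """Midpoint rounded half-away-from-zero to 0.1 cM for reports."""
        return round_report(self.position, 1)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    def statistic(self, name: str) -> float:
        if name == "mean_marker_r2":
            return self.mean_marker_r2
        return float(getattr(self, name))


def build_graph(hits: list[QtlHit]) -> nx.Graph:
    """Interval-overlap graph: nodes index hits; edges join same-LG overlapping intervals."""
    g = nx.Graph()
    usable = []
    for i, h in enumerate(hits):
        if h.lo is None or h.hi is None or math.isnan(h.lo) or math.isnan(h.hi):
            import warnings
            warnings.warn(f"QTL {i} ({h.trait}) has missing extents; excluded")
            continue
        usable.append(i)
        g.add_node(i)
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            i, j = usable[a], usable[b]
            hi_, hj = hits[i], hits[j]
            if hi_.linkage_group != hj.linkage_group:
                continue
            if max(hi_.lo, hj.lo) <= min(hi_.hi, hj.hi):
                g.add_edge(i, j)
    return g


def maximal_cliques(graph: nx.Graph, hits: list[QtlHit]) -> list[list[int]]:
    """Exact maximal-clique enumeration, deterministically ordered.

    Isolated nodes come back as singleton cliques. Output is sorted by
    (linkage group, clique left extent, member indices).
    """
    cliques = [sorted(c) for c in nx.find_cliques(graph)]

    def key(c):
        lg = hits[c[0]].linkage_group
        lo = max(hits[i].lo for i in c)
        return (lg, lo, tuple(c))

    return sorted(cliques, key=key)


def synthesize(clique: list[QtlHit]) -> MetaQtl:
    """Fuse a clique of overlapping QTL into one meta-QTL.

    Extents are the max of member left extents and min of member right
    extents (non-empty by the Helly property); the position is exactly their
    midpoint; R² and effects are arithmetic means; provenance lists are the
    sorted distinct values.
    """
    if not clique:
        raise ValueError("empty clique")
    lgs = {h.linkage_group for h in clique}
    if len(lgs) != 1:
        raise ValueError("clique spans multiple linkage groups")
    lo = max(h.lo for h in clique)
    hi = min(h.hi for h in clique)
    mean = lambda xs: sum(xs) / len(xs)
    distinct = lambda attr: sorted({getattr(h, attr) for h in clique if getattr(h, attr)})
    return MetaQtl(
        linkage_group=lgs.pop(), lo=lo, hi=hi, position=(lo + hi) / 2.0,
        members=list(clique),
        mean_marker_r2=mean([h.marker_r2 for h in clique]),
        mean_effect_maternal=mean([h.effect_maternal for h in clique]),
        mean_effect_paternal=mean([h.effect_paternal for h in clique]),
        mean_effect_interaction=mean([h.effect_interaction for h in clique]),
        traits=distinct("trait"), populations=distinct("population"),
        studies=distinct("study"), models=distinct("model"),
        methods=distinct("method"))


def assemble(hits: list[QtlHit]) -> list[MetaQtl]:
    """Graph + cliques + synthesis in one step for a pre-selected hit set."""
    graph = build_graph(hits)
    return [synthesize([hits[i] for i in c])
            for c in maximal_cliques(graph, hits)]


def stability_filter(hits: list[QtlHit], min_models: int = 3,
                     min_r2: float = 0.10) -> list[MetaQtl]:
    """Within-trait stable meta-QTL: overlap cliques per trait, kept when they
    span at least ``min_models`` distinct year models and have mean marker
    R² >= ``min_r2`` (boundary inclusive)."""
    out = []
    traits = sorted({h.trait for h in hits})
    for trait in traits:
        sub = [h for h in hits if h.trait == trait]
        for meta in assemble(sub):
            if meta.n_models >= min_models and meta.mean_marker_r2 >= min_r2:
                out.append(meta)
    return out


def apply_group_filters(metas: list[MetaQtl], group: TraitGroup
                        ) -> tuple[list[MetaQtl], list[dict]]:
    """AND-combine a group's filter rules; returns (passing metas, per-meta log)."""
    kept, log = [], []
    for meta in metas:
        verdicts = {}
        for stat, cmp, value in group.filters:
            verdicts[f"{stat}{cmp}{value}"] = bool(
                _COMPARATORS[cmp](meta.statistic(stat), value))
        ok = all(verdicts.values())
        log.append({"group": group.group_id, "linkage_group": meta.linkage_group,
                    "position": meta.position_report, "passed": ok, **verdicts})
        if ok:
            kept.append(meta)
    return kept, log


def meta_table(metas: list[MetaQtl]):
    """Meta-QTL report table mirroring the published within-trait summaries."""
    import pandas as pd

    rows = []
    for m in metas:
        rows.append({
            "traits": "+".join(m.traits),
            "models": "+".join(str(x) for x in m.models),
            "linkage_group": m.linkage_group,
            "position": m.position_report,
            "mean_marker_r2": m.mean_marker_r2,
            "lo": m.lo, "hi": m.hi,
            "methods": "+".join(m.methods),
            "mean_effect_maternal": m.mean_effect_maternal,
            "mean_effect_paternal": m.mean_effect_paternal,
            "mean_effect_interaction": m.mean_effect_interaction,
            "n_populations": m.n_populations, "n_studies": m.n_studies,
            "n_models": m.n_models, "n_methods": m.n_methods,
            "n_traits": m.n_traits,
        })
    return pd.DataFrame(rows)
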