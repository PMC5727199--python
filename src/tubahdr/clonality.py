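"""Clone matching across multi-region samples and metastasis linking.

Tumor calls from different samples of the same mouse that share an exact
(variant, barcode) pair are presumed to be regions of the same clonal
tumor; a pair shared between a primary region and a metastasis sample links
the metastasis to its source. Matching is exact - upstream denoising has
already collapsed sequencing errors - and groups are equivalence classes.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import pandas as pd

from .calling import TumorCall
from .design import InvalidInputError
from .collisions import BarcodeFrequencyModel, collision_hazard


@dataclasses.dataclass
class CloneGraph:
    graph: nx.Graph                     # nodes: (sample, variant, barcode)
    roles: dict[str, str]               # sample -> primary | metastasis
    groups: list[set[tuple[str, str, str]]]
    flagged_met_only: list[tuple[str, str]]   # (variant, barcode) of met-only groups

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for gid, group in enumerate(self.groups):
            for u, v, data in self.graph.edges(data=True):
                if u in group and v in group:
                    rows.append({"group": gid, "sample_a": u[0], "sample_b": v[0],
                                 "variant": u[1], "barcode": u[2],
                                 "type": data["type"]})
        return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b",
                                           "variant", "barcode", "type"])

    def to_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph clones {\n")
            for node, data in self.graph.nodes(data=True):
                label = f"{node[0]}\\n{node[1]}:{node[2]}"
                fh.write(f'  "{node}" [label="{label}", width={data["diameter"]:.3f}];\n')
            for u, v, data in self.graph.edges(data=True):
                style = "dashed" if data["type"] == "metastatic" else "solid"
                fh.write(f'  "{u}" -- "{v}" [style={style}];\n')
            fh.write("}\n")


def scale_sizes(calls: list[TumorCall]) -> dict[tuple[str, str, str], tuple[float, float]]:
    """Per-sample relative sizes and dot diameters.

    The largest tumor in each sample is scaled to relative size 1; dot
    diameter is the square root of relative size, so dot *area* is
    proportional to size. Sizes are reads when no absolute calibration
    exists (e.g. pancreas samples) and cells otherwise.
    """
    by_sample: dict[str, list[TumorCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    out: dict[tuple[str, str, str], tuple[float, float]] = {}
    for sample, group in by_sample.items():
        sizes = [c.cells if c.cells is not None else c.reads for c in group]
        if not sizes or max(sizes) <= 0:
            import warnings

            warnings.warn(f"sample {sample} has no positive sizes; skipped")
            continue
        m = max(sizes)
        for c, s in zip(group, sizes):
            rel = s / m
            out[(c.sample, c.variant, c.barcode)] = (rel, math.sqrt(rel))
    return out


def match_clones(samples: dict[str, list[TumorCall]],
                 roles: dict[str, str],
                 model: BarcodeFrequencyModel | None = None) -> CloneGraph:
    """Group tumor calls across samples by exact (variant, barcode) identity.

    Groups spanning >=2 primary samples get region-continuity edges; groups
    containing a metastasis get metastatic edges to every primary member
    (source ambiguity is preserved as multiple candidate edges). Met-only
    groups are flagged rather than resolved. When a frequency model is
    supplied, each cross-primary edge is annotated with the collision
    hazard: the probability the shared pair reflects two independent
    initiations rather than one clone.
    """
    if len(samples) < 2:
        raise InvalidInputError("need at least two samples")
    g = nx.Graph()
    seen: set[tuple[str, str, str]] = set()
    all_calls: list[TumorCall] = []
    for sample, calls in samples.items():
        for c in calls:
            node = (sample, c.variant, c.barcode)
            if node in seen:
                raise InvalidInputError(f"duplicate call {node}")
            seen.add(node)
            all_calls.append(c)
    diam = scale_sizes(all_calls)
    for node, (rel, d) in diam.items():
        g.add_node(node, relative_size=rel, diameter=d,
                   role=roles[node[0]])

    by_pair: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for node in g.nodes:
        by_pair.setdefault((node[1], node[2]), []).append(node)

    n_tumors = {s: len(cs) for s, cs in samples.items()}
    flagged = []
    for (variant, barcode), nodes in sorted(by_pair.items()):
        if len(nodes) < 2:
            continue
        prim = [n for n in nodes if roles[n[0]] == "primary"]
        mets = [n for n in nodes if roles[n[0]] == "metastasis"]
        if not prim:
            flagged.append((variant, barcode))
        for i, u in enumerate(prim):
            for v in prim[i + 1:]:
                hazard = None
                if model is not None and barcode in model.p.index:
                    hazard = collision_hazard(float(model.p[barcode]),
                                              n_tumors[u[0]], n_tumors[v[0]])
                g.add_edge(u, v, type="region-continuity", hazard=hazard)
        for m in mets:
            for p in prim:
                g.add_edge(p, m, type="metastatic", hazard=None)
        for i, u in enumerate(mets):   # met-met links kept, flagged above
            for v in mets[i + 1:]:
                g.add_edge(u, v, type="metastatic", hazard=None)
    groups = [set(cc) for cc in nx.connected_components(g) if len(cc) > 1]
    return CloneGraph(g, roles, groups, flagged)
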