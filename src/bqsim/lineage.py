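"""Evolutionary event logs, lineage trees and trajectory-branch clustering.

A run's evolutionary history is summarized by its events: *birth* (first
emergence of a genotype), *mutation* (any loss-of-function division),
*extinction* (a genotype's count reaching zero) and *colonization* (a
genotype's abundance first persisting above a threshold fraction).  From
these the genotype parent-child tree is built and each run is reduced to a
:class:`BranchSignature` capturing the two key random events of community
succession: whether all three one-function-loss genotypes (OFLGs) emerged
before the ancestor disappeared, and the order in which two-function-loss
genotypes (TFLGs) subsequently colonized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genotypes as gt

__all__ = [
    "EVENT_COLUMNS",
    "EvolutionEvent",
    "BranchSignature",
    "extract_events",
    "colonization_events",
    "build_tree",
    "detect_key_events",
    "cluster_branches",
    "tree_to_newick",
]

EVENT_COLUMNS = ["step", "event_type", "genotype", "parent_genotype",
                 "row", "col"]


@dataclass(frozen=True)
class EvolutionEvent:
    step: int
    event_type: str  # birth | mutation | extinction | colonization
    genotype: int
    parent_genotype: int = gt.EMPTY
    row: int = -1
    col: int = -1


def extract_events(sim_or_events) -> pd.DataFrame:
    """Normalize a Simulation, event list or DataFrame into an event table.

    The result is step-ordered with the canonical columns; consistency is
    checked (every mutation edge must lose at least one function, births
    precede extinctions).
    """
    if hasattr(sim_or_events, "event_dataframe"):
        df = sim_or_events.event_dataframe()
    elif isinstance(sim_or_events, pd.DataFrame):
        df = sim_or_events.copy()
    else:
        df = pd.DataFrame(
            [e if not isinstance(e, EvolutionEvent) else
             (e.step, e.event_type, e.genotype, e.parent_genotype, e.row, e.col)
             for e in sim_or_events],
            columns=EVENT_COLUMNS)
    df = df.sort_values("step", kind="stable").reset_index(drop=True)
    muts = df[df.event_type.isin(["mutation", "birth"])]
    for _, ev in muts.iterrows():
        parent = int(ev.parent_genotype)
        child = int(ev.genotype)
        if parent == gt.EMPTY:
            continue  # initial inoculation
        if not gt.is_subset(child, parent) or child == parent:
            raise ValueError(
                f"inconsistent event: {gt.label(child)} from {gt.label(parent)}"
            )
    for code in range(8):
        b = df[(df.genotype == code) & (df.event_type == "birth")]["step"]
        x = df[(df.genotype == code) & (df.event_type == "extinction")]["step"]
        if len(x) and (not len(b) or x.iloc[0] < b.iloc[0]):
            raise ValueError(f"extinction of {gt.label(code)} precedes birth")
    return df


def colonization_events(abundance: np.ndarray, steps: np.ndarray | None = None,
                        threshold: float = 0.05) -> list[tuple[int, int]]:
    """First step each genotype's fraction reaches >= ``threshold``.

    Parameters
    ----------
    abundance
        (n_recorded, 8) per-genotype counts over time.
    steps
        Step index of each row (defaults to the row number).
    threshold
        Persistence fraction; colonization is a stronger notion than first
        birth because most single mutants die without issue.

    Returns
    -------
    list of ``(step, genotype)`` in chronological order, one entry per
    genotype that ever colonized.
    """
    abundance = np.asarray(abundance, dtype=float)
    if steps is None:
        steps = np.arange(len(abundance))
    totals = abundance.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals[:, None] > 0, abundance / totals[:, None], 0.0)
    out = []
    for code in range(8):
        hits = np.nonzero(frac[:, code] >= threshold)[0]
        if len(hits):
            out.append((int(steps[hits[0]]), code))
    out.sort()
    return out


def build_tree(events: pd.DataFrame) -> dict:
    """Genotype lineage tree from an event table.

    Returns a dict keyed by genotype code with ``birth_step``,
    ``extinction_step`` (None if extant at run end) and ``parents``: a list
    of ``(parent_code, first_step)`` mutation edges — TFLGs and the cheater
    may carry several, having evolved from different mothers.
    """
    events = extract_events(events)
    nodes: dict[int, dict] = {}
    for _, ev in events.iterrows():
        code = int(ev.genotype)
        node = nodes.setdefault(
            code, {"birth_step": None, "extinction_step": None, "parents": []})
        if ev.event_type in ("birth", "mutation"):
            if ev.event_type == "birth" and node["birth_step"] is None:
                node["birth_step"] = int(ev.step)
            parent = int(ev.parent_genotype)
            if parent != gt.EMPTY and \
                    parent not in [p for p, _ in node["parents"]]:
                node["parents"].append((parent, int(ev.step)))
        elif ev.event_type == "extinction":
            node["extinction_step"] = int(ev.step)
    for code, node in nodes.items():
        for parent, step in node["parents"]:
            if parent not in nodes:
                raise ValueError(
                    f"child {gt.label(code)} recorded before parent "
                    f"{gt.label(parent)}")
    return nodes


def tree_to_newick(tree: dict) -> str:
    """Newick serialization of the lineage tree (first-parent edges).

    Node comments carry birth/extinction steps, e.g.
    ``111[&birth=0]``.  Multi-parent edges beyond the first are dropped
    from the topology (Newick is tree-shaped); the full edge set lives in
    the event TSV.
    """
    children: dict[int, list[int]] = {}
    roots = []
    for code, node in tree.items():
        if node["parents"]:
            first_parent = min(node["parents"], key=lambda p: p[1])[0]
            children.setdefault(first_parent, []).append(code)
        else:
            roots.append(code)

    def annot(code: int) -> str:
        node = tree[code]
        parts = []
        if node["birth_step"] is not None:
            parts.append(f"birth={node['birth_step']}")
        if node["extinction_step"] is not None:
            parts.append(f"extinction={node['extinction_step']}")
        comment = f"[&{','.join(parts)}]" if parts else ""
        return f"{gt.compact_label(code)}{comment}"

    def render(code: int) -> str:
        kids = sorted(children.get(code, []))
        if not kids:
            return annot(code)
        return "(" + ",".join(render(k) for k in kids) + ")" + annot(code)

    return ";".join(render(r) for r in sorted(roots)) + ";"


@dataclass(frozen=True)
class BranchSignature:
    """Reduction of one run to its key random events.

    ``ofg_order``: OFLGs that colonized before the ancestor's extinction,
    in colonization order.  ``ancestor_outlived_three_ofgs``: the first key
    event — all three OFLGs made it before the ancestor disappeared.
    ``tfg_order``: colonization order of TFLGs whose complement OFLG had
    colonized.  ``final_pattern``: the community label at run end.
    """

    ofg_order: tuple[int, ...]
    ancestor_outlived_three_ofgs: bool
    tfg_order: tuple[int, ...]
    final_pattern: str

    def coarse(self) -> tuple:
        """(key event 1, colonized OFLG set, first TFLG, final label)."""
        first_tfg = self.tfg_order[0] if self.tfg_order else None
        return (self.ancestor_outlived_three_ofgs, frozenset(self.ofg_order),
                first_tfg, self.final_pattern)


def detect_key_events(events: pd.DataFrame,
                      colonizations: list[tuple[int, int]],
                      final_pattern: str = "unresolved",
                      use_births: bool = False) -> BranchSignature:
    """Evaluate the two key random events of one run.

    By default emergence means *colonization* (persistence above the
    abundance threshold); ``use_births=True`` switches to raw first-birth
    events for sensitivity analysis.
    """
    events = extract_events(events)
    if use_births:
        b = events[events.event_type == "birth"]
        emergence = sorted(zip(b.step.astype(int), b.genotype.astype(int)))
    else:
        emergence = sorted(colonizations)
    ext = events[(events.event_type == "extinction")
                 & (events.genotype == gt.ANCESTOR)]["step"]
    ancestor_end = int(ext.iloc[0]) if len(ext) else None

    ofg_order = tuple(
        g for s, g in emergence if g in gt.OFLGS
        and (ancestor_end is None or s < ancestor_end))
    covered = set(ofg_order)
    tfg_order = tuple(
        g for s, g in emergence
        if g in gt.TFLGS and gt.complement(g) in covered)
    return BranchSignature(
        ofg_order=ofg_order,
        ancestor_outlived_three_ofgs=len(set(ofg_order)) == 3,
        tfg_order=tfg_order,
        final_pattern=final_pattern,
    )


def cluster_branches(signatures: list[BranchSignature],
                     coarse: bool = True) -> pd.DataFrame:
    """Group runs by branch signature; frequencies sum to 1.

    ``coarse=True`` groups by the (key event 1, OFLG set, first TFLG,
    final pattern) projection used to map trajectory branches; otherwise
    by the full signature.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    keys = [s.coarse() if coarse else s for s in signatures]
    counts = Counter(keys)
    total = sum(counts.values())
    rows = [{"signature": k, "count": n, "frequency": n / total}
            for k, n in sorted(counts.items(),
                               key=lambda kv: (-kv[1], repr(kv[0])))]
    return pd.DataFrame(rows)
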