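"""Regime paintings of trees (stochastic character maps) and SIMMAP-style I/O.

A :class:`RegimeMap` assigns an ordered sequence of ``(regime, duration)``
segments to every branch, rootward end first, so that a full history of a
discrete character (here: oviparous vs viviparous parity mode) is recorded,
not just the tip states. The on-disk format is the SIMMAP-style annotated
Newick in which each branch length is replaced by ``{state,dur:state,dur}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import PhyloTree

__all__ = ["RegimeMap", "write_simmap", "read_simmap"]

SEGMENT_ATOL_FACTOR = 1e-9  # abs tolerance on segment sums, times tree height


@dataclass
class RegimeMap:
    """A piecewise-constant regime history painted onto a tree.

    Parameters
    ----------
    tree : PhyloTree
    segments : list of list of (str, float)
        ``segments[u]`` paints the branch subtending node ``u``, ordered from
        the rootward end to the tipward end; empty for the root.
    root_state : str
        Regime at the root node.
    """

    tree: PhyloTree
    segments: list
    root_state: str

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        atol = SEGMENT_ATOL_FACTOR * max(self.tree.height, 1.0)
        if len(self.segments) != self.tree.n_nodes:
            raise ValueError("one segment list per node required")
        for u in range(self.tree.n_nodes):
            if u == self.tree.root:
                continue
            segs = self.segments[u]
            if not segs:
                raise ValueError(f"branch above node {u} is unpainted")
            total = sum(d for _, d in segs)
            if abs(total - self.tree.lengths[u]) > atol:
                raise ValueError(
                    f"segments on branch {u} sum to {total}, "
                    f"branch length is {self.tree.lengths[u]}"
                )
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise ValueError(f"adjacent equal-regime segments on branch {u}")
            start = segs[0][0]
            if start != self.node_state(self.tree.parent[u]):
                raise ValueError(f"branch {u} does not start in its parent's regime")

    # -------------------------------------------------------------- queries
    def node_state(self, u: int) -> str:
        """Regime at (the tipward end of the branch above) node ``u``."""
        if u == self.tree.root:
            return self.root_state
        return self.segments[u][-1][0]

    @property
    def regimes(self) -> list[str]:
        labs = {self.root_state}
        for u in range(self.tree.n_nodes):
            labs.update(s for s, _ in self.segments[u])
        return sorted(labs)

    def tip_states(self) -> dict:
        return {self.tree.labels[t]: self.node_state(int(t)) for t in self.tree.tips}

    def transition_counts(self) -> dict:
        """Number of regime changes by (from, to) direction, over all branches."""
        counts: dict = {}
        for u in range(self.tree.n_nodes):
            segs = self.segments[u]
            for (a, _), (b, _) in zip(segs, segs[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        return counts

    def n_transitions(self) -> int:
        return sum(self.transition_counts().values())

    def path_segments(self, tip_label: str):
        """Regime intervals ``(t0, t1, regime)`` in absolute time from the
        root, along the root-to-tip path, rootward first."""
        tip = int(self.tree.tips[self.tree.tip_index(tip_label)])
        out = []
        for u in self.tree.path_to_tip(tip):
            t = float(self.tree.depths[self.tree.parent[u]])
            for lab, dur in self.segments[u]:
                out.append((t, t + dur, lab))
                t += dur
        return out

    def time_in_regime(self) -> dict:
        tot: dict = {}
        for u in range(self.tree.n_nodes):
            for lab, dur in self.segments[u]:
                tot[lab] = tot.get(lab, 0.0) + dur
        return tot

    # ------------------------------------------------------------ construct
    @classmethod
    def from_histories(cls, tree: PhyloTree, root_state: str, histories: dict) -> "RegimeMap":
        """Build a map from per-branch change lists.

        ``histories[u]`` is a list of ``(time_from_branch_start, new_state)``
        events on the branch above node ``u``, sorted by time.
        """
        node_state = {tree.root: root_state}
        segments: list = [[] for _ in range(tree.n_nodes)]
        for u in tree.preorder:
            if u == tree.root:
                continue
            state = node_state[tree.parent[u]]
            t_prev = 0.0
            segs = []
            for t_ev, new_state in histories.get(u, []):
                segs.append((state, t_ev - t_prev))
                state, t_prev = new_state, t_ev
            segs.append((state, tree.lengths[u] - t_prev))
            segments[u] = [(s, d) for s, d in segs if d > 0 or len(segs) == 1]
            if not segments[u]:
                segments[u] = [(state, 0.0)]
            node_state[u] = state
        return cls(tree, segments, root_state)

    @classmethod
    def single_regime(cls, tree: PhyloTree, regime: str) -> "RegimeMap":
        segs = [[] if u == tree.root else [(regime, float(tree.lengths[u]))]
                for u in range(tree.n_nodes)]
        return cls(tree, segs, regime)

    # --------------------------------------------------------------- pruning
    def prune_to(self, keep_labels) -> "RegimeMap":
        """Restrict the painting to a tip subset.

        Unifurcations are suppressed by concatenating the segment lists of the
        merged branches (adjacent equal regimes fused), and the stem above the
        MRCA of the kept tips is dropped, matching :meth:`PhyloTree.prune_to`.
        """
        tree = self.tree
        keep_tips = {int(tree.tips[tree.tip_index(l)]) for l in keep_labels}
        has_keep = np.zeros(tree.n_nodes, dtype=bool)
        for u in tree.postorder:
            if u in keep_tips:
                has_keep[u] = True
            has_keep[u] |= any(has_keep[c] for c in tree.children[u])
        if not has_keep[tree.root]:
            raise ValueError("no kept tips")
        # descend to the MRCA of kept tips
        mrca = tree.root
        while mrca not in keep_tips:
            kept_kids = [c for c in tree.children[mrca] if has_keep[c]]
            if len(kept_kids) != 1:
                break
            mrca = kept_kids[0]

        new_parent: list[int] = []
        new_lengths: list[float] = []
        new_labels: list = []
        new_segments: list = []

        def merge(segs):
            out: list = []
            for lab, dur in segs:
                if out and out[-1][0] == lab:
                    out[-1] = (lab, out[-1][1] + dur)
                else:
                    out.append((lab, dur))
            return out

        def add_node(parent_idx, length, label, segs):
            new_parent.append(parent_idx)
            new_lengths.append(length)
            new_labels.append(label)
            new_segments.append(segs)
            return len(new_parent) - 1

        root_idx = add_node(-1, 0.0, tree.labels[mrca] if mrca in keep_tips else None, [])
        stack = [(mrca, root_idx)]
        while stack:
            u, pu = stack.pop()
            for c in tree.children[u]:
                if not has_keep[c]:
                    continue
                segs = list(self.segments[c])
                v = c
                while v not in keep_tips:
                    kept = [k for k in tree.children[v] if has_keep[k]]
                    if len(kept) != 1:
                        break
                    v = kept[0]
                    segs += self.segments[v]
                segs = merge(segs)
                idx = add_node(pu, sum(d for _, d in segs), tree.labels[v], segs)
                stack.append((v, idx))
        new_tree = PhyloTree(new_parent, new_lengths, new_labels)
        return RegimeMap(new_tree, new_segments, self.node_state(mrca))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<RegimeMap {self.tree.n_tips} tips, regimes {self.regimes}, "
                f"{self.n_transitions()} transitions>")


# --------------------------------------------------------------------- I/O
def _simmap_annotation(segs) -> str:
    return "{" + ":".join(f"{lab},{dur:.17g}" for lab, dur in segs) + "}"


def _write_one(rmap: RegimeMap) -> str:
    tree = rmap.tree

    def rec(u: int) -> str:
        if not tree.children[u]:
            body = tree.labels[u]
        else:
            body = "(" + ",".join(rec(c) for c in tree.children[u]) + ")"
        if u == tree.root:
            return body + ";"
        return body + ":" + _simmap_annotation(rmap.segments[u])

    return rec(tree.root)


def write_simmap(maps, path) -> None:
    """Write one or more regime maps as SIMMAP-style annotated Newick.

    One tree per line; segments on each branch are listed rootward first.
    """
    if isinstance(maps, RegimeMap):
        maps = [maps]
    with open(path, "w") as fh:
        for m in maps:
            fh.write(_write_one(m) + "\n")


class _SimmapParser:
    """Minimal recursive-descent parser for the annotated-Newick regime maps
    written by :func:`write_simmap` (no Python library reads this dialect)."""

    def __init__(self, text: str):
        self.s = text.strip()
        self.pos = 0
        self.parent: list[int] = []
        self.lengths: list[float] = []
        self.labels: list = []
        self.segments: list = []

    def error(self, msg):
        raise ValueError(f"simmap parse error at char {self.pos}: {msg} "
                         f"(near {self.s[self.pos:self.pos + 20]!r})")

    def _new_node(self, parent):
        self.parent.append(parent)
        self.lengths.append(0.0)
        self.labels.append(None)
        self.segments.append([])
        return len(self.parent) - 1

    def parse(self):
        root = self._node(-1)
        if self.pos >= len(self.s) or self.s[self.pos] != ";":
            self.error("expected ';'")
        tree = PhyloTree(self.parent, self.lengths, self.labels)
        # node ids line up because PhyloTree preserves input indexing
        segs = self.segments
        root_state = None
        for c in range(len(self.parent)):
            if self.parent[c] == root and segs[c]:
                root_state = segs[c][0][0]
                break
        return RegimeMap(tree, segs, root_state)

    def _node(self, parent):
        idx = self._new_node(parent)
        if self.s[self.pos] == "(":
            self.pos += 1
            while True:
                self._node(idx)
                if self.pos >= len(self.s):
                    self.error("unterminated clade")
                if self.s[self.pos] == ",":
                    self.pos += 1
                    continue
                if self.s[self.pos] == ")":
                    self.pos += 1
                    break
                self.error("expected ',' or ')'")
        label = self._until(":,();{")
        if label:
            self.labels[idx] = label
        if self.pos < len(self.s) and self.s[self.pos] == ":":
            self.pos += 1
            if self.s[self.pos] != "{":
                self.error("expected '{' opening a segment annotation")
            self.pos += 1
            body = self._until("}")
            self.pos += 1  # consume '}'
            segs = []
            for part in body.split(":"):
                lab, dur = part.split(",")
                segs.append((lab, float(dur)))
            self.segments[idx] = segs
            self.lengths[idx] = sum(d for _, d in segs)
        elif parent != -1:
            self.error("branch without a segment annotation")
        return idx

    def _until(self, stop_chars):
        start = self.pos
        while self.pos < len(self.s) and self.s[self.pos] not in stop_chars:
            self.pos += 1
        return self.s[start:self.pos]


def read_simmap(path) -> list[RegimeMap]:
    """Read regime maps written by :func:`write_simmap` (one per line)."""
    maps = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                maps.append(_SimmapParser(line).parse())
    return maps
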