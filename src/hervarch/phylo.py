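"""Distance-based phylogeny: progressive MSA, p-distance, neighbor joining.

At the divergence scales handled here (repeat copies a few percent apart)
grouping structure is what matters, and neighbor joining on p-distances
recovers it; NJ is exactly consistent on additive distance matrices. Both
nucleotide and amino-acid inputs share the machinery; only the alphabet and
the substitution matrix behind the progressive alignment differ.

Negative NJ branch-length estimates are clamped to zero (standard practice)
with a log note. Pair selection ties are broken on the lexicographically
smallest leaf label under each node, which makes the tree invariant to input
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from biotite.sequence import NucleotideSequence, ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_multiple

logger = logging.getLogger("hervarch")

_GAP = (-10, -1)

_NT_CHARS = set("ACGTN")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    name: str | None = None
    children: tuple[tuple["TreeNode", float], ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def min_leaf(self) -> str:
        return min(self.leaves())


@dataclass(frozen=True)
class PhyloTree:
    root: TreeNode

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaves()))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    labels: tuple[str, ...]
    rows: tuple[str, ...]  # gapped sequences, all the same length

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace("-", "")


def _validate_alphabet(seq: str, alphabet: str, label: str) -> str:
    seq = seq.upper()
    valid = _NT_CHARS if alphabet == "nt" else _AA_CHARS
    bad = set(seq) - valid
    if bad:
        raise ValueError(f"{label}: invalid {alphabet} characters {sorted(bad)}")
    return seq


def progressive_msa(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    alphabet: str = "nt",
) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment (desk-scale MAFFT stand-in)."""
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    labels = tuple(name for name, _ in items)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    seqs = []
    for name, seq in items:
        seq = _validate_alphabet(seq, alphabet, name)
        seqs.append(NucleotideSequence(seq) if alphabet == "nt" else ProteinSequence(seq))
    matrix = (
        SubstitutionMatrix.std_nucleotide_matrix()
        if alphabet == "nt"
        else SubstitutionMatrix.std_protein_matrix()
    )
    if len(items) == 2:
        from biotite.sequence.align import align_optimal

        aln = align_optimal(seqs[0], seqs[1], matrix, gap_penalty=_GAP)[0]
        rows = tuple(aln.get_gapped_sequences())
    else:
        alignment, _, _, _ = align_multiple(seqs, matrix, gap_penalty=_GAP)
        rows = tuple(alignment.get_gapped_sequences())
    msa = MultipleAlignment(labels=labels, rows=rows)
    for name, seq in items:
        if msa.ungapped(name) != seq.upper():
            raise AssertionError(f"alignment row for {name} does not reproduce input")
    return msa


def p_distance(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise fraction of mismatched columns among columns where neither
    row is gapped."""
    n = len(alignment.labels)
    arr = np.array([list(r) for r in alignment.rows])
    gaps = arr == "-"
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gaps[i] | gaps[j])
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.labels[i]} "
                    f"and {alignment.labels[j]}"
                )
            d = float((arr[i][comparable] != arr[j][comparable]).sum()) / m
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=alignment.labels, values=values)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.4g at %s clamped to 0", length, context)
        return 0.0
    return length


def neighbor_joining(
    dm: DistanceMatrix, outgroup: str | None = None
) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken on the lexicographically smallest pair
    of minimum leaf labels. If ``outgroup`` is given the tree is rooted on
    the midpoint of the outgroup's pendant edge.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in dm.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    keys: list[str] = list(dm.labels)
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = d[i, j]
        bi = _clamp(0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)), keys[i])
        bj = _clamp(dij - bi, keys[j])
        new_node = TreeNode(children=((nodes[i], bi), (nodes[j], bj)))
        new_key = min(keys[i], keys[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [new_key]

    # final three-point join
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    ba = _clamp(0.5 * (dab + dac - dbc), keys[0])
    bb = _clamp(0.5 * (dab + dbc - dac), keys[1])
    bc = _clamp(0.5 * (dac + dbc - dab), keys[2])
    joined = sorted(zip((ba, bb, bc), keys, (a, b, c)), key=lambda t: t[1])
    root = TreeNode(children=tuple((node, bl) for bl, _, node in joined))
    tree = PhyloTree(root=root)
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def _adjacency(node: TreeNode, adj: dict, counter: list) -> object:
    """Undirected edge map of a rooted tree; internal nodes get fresh ids."""
    if node.is_leaf:
        key = node.name
    else:
        key = ("internal", counter[0])
        counter[0] += 1
    adj.setdefault(key, [])
    for child, length in node.children:
        ckey = _adjacency(child, adj, counter)
        adj[key].append((ckey, length))
        adj[ckey].append((key, length))
    return key


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Re-root an (effectively unrooted) tree on the outgroup pendant edge."""
    if outgroup not in tree.root.leaves():
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    adj: dict = {}
    _adjacency(tree.root, adj, [0])

    def build(key, parent) -> TreeNode:
        children = []
        for nkey, length in adj[key]:
            if nkey == parent:
                continue
            children.append((build(nkey, key), length))
        if not children:
            return TreeNode(name=key)
        if isinstance(key, tuple):
            return TreeNode(children=tuple(children))
        # a leaf used as an internal passage point cannot occur for pendant edges
        return TreeNode(name=key, children=tuple(children))

    (neighbor, pendant) = adj[outgroup][0]
    ingroup = build(neighbor, outgroup)
    root = TreeNode(
        children=(
            (TreeNode(name=outgroup), pendant / 2),
            (ingroup, pendant / 2),
        )
    )
    return PhyloTree(root=root)


def tree_from_sequences(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    alphabet: str = "nt",
    outgroup: str | None = None,
) -> tuple[PhyloTree, DistanceMatrix, MultipleAlignment]:
    """Align, compute p-distances, and build the NJ tree in one call."""
    msa = progressive_msa(sequences, alphabet=alphabet)
    dm = p_distance(msa)
    return neighbor_joining(dm, outgroup=outgroup), dm, msa
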