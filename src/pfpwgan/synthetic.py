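"""Desk-scale synthetic benchmark with the statistical structure the model
exploits: DAG-organized labels, motif-determined term membership, true-path
closure, and planted co-occurrence / mutual-exclusion between leaf terms.

Each leaf term carries a short exact sequence motif; a protein annotated
with a leaf contains that leaf's motif, and annotations are closed upward
under the true-path rule.  Planted pair constraints act on leaf terms only:
a rho=+1 pair always co-occurs (observing either member implies the other)
and a rho=-1 pair never co-occurs.  Internal-term co-occurrence then arises
from propagation, so the ground-truth heatmap carries relations beyond the
DAG itself — the structure the adversarial critic is meant to discover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationMatrix
from .encoding import ALPHABET, ProteinRecord, write_fasta
from .go_dag import OntologyDag, propagate_true_path, write_obo
from .metrics import cooccurrence_heatmap

__all__ = ["SynthSpec", "SynthDataset", "sample_dag", "sample_proteins",
           "sample_feature_dataset", "write_dataset"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic benchmark.

    ``co_pairs`` lists (leaf, leaf, rho) constraints with rho=+1 forcing
    co-occurrence and rho=-1 forcing mutual exclusion; by default three
    pairs of each kind are planted on distinct leaves.
    """

    n_terms: int = 40
    dag_depth: int = 4
    n_proteins: int = 2000
    seq_len: tuple = (50, 400)
    motif_len: int = 6
    motifs_per_leaf: int = 1
    n_co_pairs: int = 3
    n_excl_pairs: int = 3
    co_pairs: list | None = None
    max_leaves_per_protein: int = 3
    noise: float = 0.0
    namespace: str = "BP"
    feature_dim: int = 64
    feature_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < self.dag_depth + 1:
            raise ValueError("n_terms must exceed dag_depth")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")
        if self.motif_len < 1 or self.seq_len[0] < self.motif_len:
            raise ValueError("sequences must be able to hold one motif")


@dataclass
class SynthDataset:
    dag: OntologyDag
    records: list
    annotations: AnnotationMatrix
    truth_heatmap: np.ndarray
    ledger: dict = field(default_factory=dict)


def sample_dag(spec: SynthSpec, rng: np.random.Generator | None = None) -> OntologyDag:
    """Random single-root DAG: every non-root term has one parent on the
    level above (so term height equals its level) and, with probability 1/2,
    a second parent from any strictly shallower level."""
    rng = rng or np.random.default_rng(spec.seed)
    n_inner = spec.n_terms - 1
    base = n_inner // spec.dag_depth
    sizes = [base] * spec.dag_depth
    for i in range(n_inner - base * spec.dag_depth):
        sizes[-(i % spec.dag_depth) - 1] += 1
    if min(sizes) < 1:
        raise ValueError("cannot fill every level: too few terms for dag_depth")
    terms = [f"GO:{i + 1:07d}" for i in range(spec.n_terms)]
    levels = [[terms[0]]]
    k = 1
    for s in sizes:
        levels.append(terms[k:k + s])
        k += s
    parents = {terms[0]: set()}
    for lvl in range(1, len(levels)):
        for t in levels[lvl]:
            ps = {levels[lvl - 1][rng.integers(len(levels[lvl - 1]))]}
            if lvl > 1 and rng.random() < 0.5:
                shallow = rng.integers(1, lvl)
                cand = [u for u in levels[shallow] if u not in ps]
                if cand:
                    ps.add(cand[rng.integers(len(cand))])
            parents[t] = ps
    namespace = {t: spec.namespace for t in terms}
    names = {t: f"synthetic term {i}" for i, t in enumerate(terms)}
    return OntologyDag(terms, namespace, parents, names)


def _pair_constraints(spec: SynthSpec, leaves, rng) -> list:
    if spec.co_pairs is not None:
        for a, b, rho in spec.co_pairs:
            if a not in leaves or b not in leaves:
                raise ValueError("co_pairs must reference leaf terms")
        return list(spec.co_pairs)
    need = 2 * (spec.n_co_pairs + spec.n_excl_pairs)
    if len(leaves) < need:
        raise ValueError(f"need {need} distinct leaves for pair constraints, "
                         f"have {len(leaves)}")
    chosen = rng.choice(len(leaves), size=need, replace=False)
    it = iter(chosen)
    pairs = []
    for _ in range(spec.n_co_pairs):
        pairs.append((leaves[next(it)], leaves[next(it)], 1))
    for _ in range(spec.n_excl_pairs):
        pairs.append((leaves[next(it)], leaves[next(it)], -1))
    return pairs


def _sample_motifs(leaves, spec: SynthSpec, rng) -> dict:
    motifs: dict[str, str] = {}
    seen = set()
    letters = np.array(list(ALPHABET))
    for leaf in leaves:
        for _ in range(100):
            m = "".join(rng.choice(letters, size=spec.motif_len))
            if m not in seen:
                seen.add(m)
                motifs[leaf] = m
                break
        else:
            raise RuntimeError("could not sample distinct motifs")
    return motifs


def _draw_leaf_sets(spec: SynthSpec, leaves, pairs, rng, n: int) -> list:
    co = {a: b for a, b, r in pairs if r == 1} | {b: a for a, b, r in pairs if r == 1}
    excl = [(a, b) for a, b, r in pairs if r == -1]
    out = []
    for _ in range(n):
        m = int(rng.integers(1, spec.max_leaves_per_protein + 1))
        picked = set(np.asarray(leaves, dtype=object)[rng.choice(len(leaves), size=m, replace=False)])
        for a, b in excl:  # mutual exclusion: drop one member if both drawn
            if a in picked and b in picked:
                picked.remove(a if rng.random() < 0.5 else b)
        for t in list(picked):  # forced co-occurrence closure
            if t in co:
                picked.add(co[t])
        out.append(sorted(picked))
    return out


def _plant(seq: np.ndarray, motifs: list, rng) -> list:
    """Place motifs at random non-overlapping positions.

    Uses the gap construction (sorted uniform gap offsets plus cumulative
    motif lengths), which always succeeds when the sequence can hold the
    motifs; returns a (motif, start) list.
    """
    L = len(seq)
    total = sum(len(m) for m in motifs)
    if total > L:
        raise RuntimeError("sequence too short to place motifs without overlap")
    order = rng.permutation(len(motifs))
    gaps = np.sort(rng.integers(0, L - total + 1, size=len(motifs)))
    placed, offset = [], 0
    for g, k in zip(gaps, order):
        m = motifs[int(k)]
        s = int(g) + offset
        seq[s:s + len(m)] = list(m)
        placed.append((m, s))
        offset += len(m)
    return placed


def sample_proteins(spec: SynthSpec, dag: OntologyDag,
                    rng: np.random.Generator | None = None) -> SynthDataset:
    """Generate motif-bearing sequences with true-path-closed annotations."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    leaves = sorted(dag.leaves())
    pairs = _pair_constraints(spec, leaves, rng)
    motifs = _sample_motifs(leaves, spec, rng)
    leaf_sets = _draw_leaf_sets(spec, leaves, pairs, rng, spec.n_proteins)
    letters = np.array(list(ALPHABET))
    records, ledger_rows, pairs_list = [], {}, []
    lo, hi = spec.seq_len
    for i, leaf_set in enumerate(leaf_sets):
        pid = f"P{i + 1:05d}"
        need = spec.motif_len * len(leaf_set)
        L = int(rng.integers(max(lo, need), hi + 1))
        seq = rng.choice(letters, size=L)
        placed = _plant(seq, [motifs[t] for t in leaf_set], rng)
        sequence = "".join(seq)
        for m, s in placed:
            assert sequence[s:s + len(m)] == m
        records.append(ProteinRecord(pid, sequence))
        ledger_rows[pid] = {"leaves": leaf_set, "motifs": placed}
        pairs_list.extend((pid, t) for t in leaf_set)
    ann = AnnotationMatrix.from_pairs(
        pairs_list, proteins=[r.id for r in records], terms=list(dag.terms))
    ann = propagate_true_path(dag, ann)
    if spec.noise > 0.0:
        flips = rng.random(ann.values.shape) < spec.noise
        ann = AnnotationMatrix(ann.proteins, ann.terms,
                               np.where(flips, 1 - ann.values, ann.values))
    ledger = {
        "pairs": [[a, b, int(r)] for a, b, r in pairs],
        "motifs": motifs,
        "proteins": ledger_rows,
    }
    return SynthDataset(dag, records, ann, cooccurrence_heatmap(ann), ledger)


def sample_feature_dataset(spec: SynthSpec, dag: OntologyDag,
                           rng: np.random.Generator | None = None):
    """Feature-vector variant: per-leaf prototype vectors summed per protein
    plus isotropic noise.  Returns ``(feature matrix, annotations, ledger)``."""
    rng = rng or np.random.default_rng(spec.seed + 2)
    leaves = sorted(dag.leaves())
    pairs = _pair_constraints(spec, leaves, rng)
    protos = {t: rng.normal(0.0, 1.0, size=spec.feature_dim) for t in leaves}
    leaf_sets = _draw_leaf_sets(spec, leaves, pairs, rng, spec.n_proteins)
    X = np.zeros((spec.n_proteins, spec.feature_dim))
    pairs_list, proteins = [], []
    for i, leaf_set in enumerate(leaf_sets):
        pid = f"P{i + 1:05d}"
        proteins.append(pid)
        X[i] = sum(protos[t] for t in leaf_set)
        X[i] += spec.feature_noise * rng.normal(size=spec.feature_dim)
        pairs_list.extend((pid, t) for t in leaf_set)
    ann = AnnotationMatrix.from_pairs(pairs_list, proteins=proteins, terms=list(dag.terms))
    ann = propagate_true_path(dag, ann)
    ledger = {"pairs": [[a, b, int(r)] for a, b, r in pairs],
              "leaf_sets": {p: s for p, s in zip(proteins, leaf_sets)}}
    return X, ann, ledger


def write_dataset(ds: SynthDataset, out_dir) -> None:
    """Emit seqs.fa, ontology.obo, annotations.tsv, truth_heatmap.tsv, ledger.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, out / "seqs.fa")
    write_obo(ds.dag, out / "ontology.obo")
    ds.annotations.to_tsv(out / "annotations.tsv")
    np.savetxt(out / "truth_heatmap.tsv", ds.truth_heatmap, fmt="%d", delimiter="\t")
    with open(out / "ledger.json", "w") as fh:
        json.dump(ds.ledger, fh, indent=1)
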