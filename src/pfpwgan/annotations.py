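"""Protein-by-term annotation matrices (the assignment vectors ``y``)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AnnotationMatrix", "read_annotation_pairs"]


@dataclass
class AnnotationMatrix:
    """Binary proteins x terms assignment matrix.

    ``values[i, j] == 1`` iff protein ``proteins[i]`` is annotated with term
    ``terms[j]``.
    """

    proteins: list
    terms: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.proteins), len(self.terms)):
            raise ValueError("values shape does not match protein/term lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation matrix must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def term_index(self) -> dict:
        return {t: j for j, t in enumerate(self.terms)}

    @classmethod
    def from_pairs(cls, pairs, proteins=None, terms=None) -> "AnnotationMatrix":
        """Build from (protein_id, term_id) pairs.

        Row/column universes default to the sorted ids seen in the pairs but
        can be fixed explicitly to align with other matrices.
        """
        pairs = list(pairs)
        if proteins is None:
            proteins = sorted({p for p, _ in pairs})
        if terms is None:
            terms = sorted({t for _, t in pairs})
        pi = {p: i for i, p in enumerate(proteins)}
        ti = {t: j for j, t in enumerate(terms)}
        values = np.zeros((len(proteins), len(terms)), dtype=np.int8)
        for p, t in pairs:
            values[pi[p], ti[t]] = 1
        return cls(list(proteins), list(terms), values)

    @classmethod
    def from_tsv(cls, path, proteins=None, terms=None) -> "AnnotationMatrix":
        df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "term_id"],
                         dtype=str, comment="#")
        return cls.from_pairs(df.itertuples(index=False, name=None), proteins, terms)

    def to_tsv(self, path) -> None:
        rows, cols = np.nonzero(self.values)
        with open(path, "w") as fh:
            for i, j in zip(rows, cols):
                fh.write(f"{self.proteins[i]}\t{self.terms[j]}\n")

    def subset_terms(self, keep_terms) -> "AnnotationMatrix":
        idx = [self.term_index[t] for t in keep_terms]
        return AnnotationMatrix(list(self.proteins), list(keep_terms), self.values[:, idx])

    def subset_proteins(self, keep_proteins) -> "AnnotationMatrix":
        pi = {p: i for i, p in enumerate(self.proteins)}
        idx = [pi[p] for p in keep_proteins]
        return AnnotationMatrix(list(keep_proteins), list(self.terms), self.values[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnotationMatrix)
            and self.proteins == other.proteins
            and self.terms == other.terms
            and np.array_equal(self.values, other.values)
        )


def read_annotation_pairs(path):
    """Yield (protein_id, term_id) pairs from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "term_id"],
                     dtype=str, comment="#")
    return list(df.itertuples(index=False, name=None))
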