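"""Elementary penetrance models M1-M5, combined models, and their partitions.

An elementary model binds one of five penetrance templates to one or two
loci and thereby partitions the individuals into classes of equal disease
probability:

* ``M1(j)`` - full single-locus model, one class per genotype (3 classes);
* ``M2(j)`` - dominant single-locus model, carrier vs non-carrier (2);
* ``M3(j,k)`` - full two-locus model, one class per genotype pair (9);
* ``M4(j,k)`` - dominant two-locus model with main effects (4);
* ``M5(j,k)`` - dominant two-locus pure-interaction model: both-carrier vs
  the rest (2).

A combined model is a conflict-free set of elementary models (no locus in
more than one component); its partition is the product (all intersections)
of the component partitions, so the class count is the product of the
component class counts.  The empty combination is the null model M0 with a
single class.

For model identity, M3(j,k) is expanded to {M1(j), M1(k)} and M4(j,k) to
{M2(j), M2(k)}: those pairs induce identical partitions, hence identical
marginal likelihoods and priors, and must not be double-counted when model
posteriors are averaged over the set of distinct visited models.  M3 and M4
remain available as single proposal moves for the search.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementaryModel",
    "CombinedModel",
    "Partition",
    "ModelConflictError",
    "elementary_partition",
    "combine",
    "enumerate_elementary",
    "canonical_key",
    "model_from_string",
]

_N_CLASSES = {"M1": 3, "M2": 2, "M3": 9, "M4": 4, "M5": 2}
_ARITY = {"M1": 1, "M2": 1, "M3": 2, "M4": 2, "M5": 2}


class ModelConflictError(ValueError):
    """Raised when elementary models with overlapping loci are combined."""


@dataclass(frozen=True)
class ElementaryModel:
    """One of the five penetrance templates bound to specific loci.

    Loci are 0-based indices into the genotype matrix; two-locus models
    store their indices in ascending order.
    """

    kind: str
    loci: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in _N_CLASSES:
            raise ValueError(f"unknown elementary model kind {self.kind!r}")
        loci = tuple(int(j) for j in self.loci)
        if len(loci) != _ARITY[self.kind]:
            raise ValueError(f"{self.kind} takes {_ARITY[self.kind]} locus indices")
        if len(loci) == 2:
            if loci[0] == loci[1]:
                raise ValueError("two-locus model needs two distinct loci")
            loci = tuple(sorted(loci))
        object.__setattr__(self, "loci", loci)

    @property
    def n_classes(self) -> int:
        return _N_CLASSES[self.kind]

    def class_labels(self, genotypes: np.ndarray) -> np.ndarray:
        """Class index of every individual under this model's partition."""
        z = genotypes
        if self.kind == "M1":
            return z[:, self.loci[0]].astype(np.int64)
        if self.kind == "M2":
            return (z[:, self.loci[0]] > 0).astype(np.int64)
        j, k = self.loci
        if self.kind == "M3":
            return 3 * z[:, j].astype(np.int64) + z[:, k]
        if self.kind == "M4":
            return 2 * (z[:, j] > 0).astype(np.int64) + (z[:, k] > 0)
        return ((z[:, j] > 0) & (z[:, k] > 0)).astype(np.int64)  # M5

    def __str__(self) -> str:
        inside = ",".join(str(j + 1) for j in self.loci)  # 1-based for humans
        return f"{self.kind}({inside})"


def _sort_key(m: ElementaryModel):
    return (m.loci, m.kind)


def _canonical_components(models) -> tuple[ElementaryModel, ...]:
    out = []
    for m in models:
        if m.kind == "M3":
            out += [ElementaryModel("M1", (m.loci[0],)), ElementaryModel("M1", (m.loci[1],))]
        elif m.kind == "M4":
            out += [ElementaryModel("M2", (m.loci[0],)), ElementaryModel("M2", (m.loci[1],))]
        else:
            out.append(m)
    return tuple(sorted(out, key=_sort_key))


@dataclass(frozen=True)
class CombinedModel:
    """A conflict-free set of elementary models in canonical form.

    ``components`` contain no M3/M4 (those are stored expanded) and are
    sorted by (loci, kind).  The empty tuple is the null model M0.
    """

    components: tuple[ElementaryModel, ...]

    def __post_init__(self):
        comps = _canonical_components(self.components)
        seen: set[int] = set()
        for m in comps:
            for j in m.loci:
                if j in seen:
                    raise ModelConflictError(
                        f"locus {j + 1} appears in more than one component"
                    )
                seen.add(j)
        object.__setattr__(self, "components", comps)

    @property
    def loci(self) -> frozenset[int]:
        return frozenset(j for m in self.components for j in m.loci)

    @property
    def n_loci(self) -> int:
        """Number of distinct SNPs in the model (the prior's exponent)."""
        return sum(len(m.loci) for m in self.components)

    @property
    def n_classes(self) -> int:
        d = 1
        for m in self.components:
            d *= m.n_classes
        return d

    def class_labels(self, genotypes: np.ndarray) -> np.ndarray:
        """Mixed-radix product-partition label for every individual."""
        labels = np.zeros(genotypes.shape[0], dtype=np.int64)
        for m in self.components:
            labels = labels * m.n_classes + m.class_labels(genotypes)
        return labels

    def key(self) -> str:
        return canonical_key(self)

    def __str__(self) -> str:
        if not self.components:
            return "M0"
        return "+".join(str(m) for m in self.components)


@dataclass
class Partition:
    """Assignment of each individual to one of ``n_classes`` structural
    classes; classes may be empty (they are score-neutral)."""

    class_of: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.class_of = np.asarray(self.class_of, dtype=np.int64)
        if self.class_of.size and (
            self.class_of.min() < 0 or self.class_of.max() >= self.n_classes
        ):
            raise ValueError("class labels out of range")


def elementary_partition(model: ElementaryModel, table) -> Partition:
    """Partition induced by a single elementary model on a genotype table."""
    genotypes = table.genotypes if hasattr(table, "genotypes") else np.asarray(table)
    if max(model.loci) >= genotypes.shape[1]:
        raise IndexError("model locus out of range for table")
    return Partition(model.class_labels(genotypes), model.n_classes)


def combine(models, table) -> tuple[CombinedModel, Partition]:
    """Combine elementary models with pairwise-disjoint loci.

    Returns the canonical combined model and the product partition (all
    intersections of component classes, mixed-radix labelled).  Overlapping
    loci raise :class:`ModelConflictError`.
    """
    genotypes = table.genotypes if hasattr(table, "genotypes") else np.asarray(table)
    cm = CombinedModel(tuple(models))
    if cm.loci and max(cm.loci) >= genotypes.shape[1]:
        raise IndexError("model locus out of range for table")
    return cm, Partition(cm.class_labels(genotypes), cm.n_classes)


def enumerate_elementary(n_loci: int) -> list[ElementaryModel]:
    """All distinct elementary models on ``n_loci`` loci.

    2L single-locus models plus 3*C(L,2) two-locus models.
    """
    out = [ElementaryModel(kind, (j,)) for j in range(n_loci) for kind in ("M1", "M2")]
    for j, k in itertools.combinations(range(n_loci), 2):
        out += [ElementaryModel(kind, (j, k)) for kind in ("M3", "M4", "M5")]
    return out


def canonical_key(model: CombinedModel | tuple) -> str:
    """Stable identity string: equal iff the models induce the same
    partition on every genotype table (after M3/M4 expansion)."""
    if not isinstance(model, CombinedModel):
        model = CombinedModel(tuple(model))
    return str(model)


_ELEM_RE = re.compile(r"(M[1-5])\((\d+)(?:,(\d+))?\)")


def model_from_string(text: str) -> CombinedModel:
    """Parse the compact notation, e.g. ``"M2(3)+M5(12,47)"``; locus indices
    in the text are 1-based.  ``"M0"`` is the null model."""
    text = text.strip()
    if text == "M0":
        return CombinedModel(())
    comps = []
    for part in text.split("+"):
        m = _ELEM_RE.fullmatch(part.strip())
        if not m:
            raise ValueError(f"cannot parse elementary model {part!r}")
        kind, a, b = m.group(1), m.group(2), m.group(3)
        loci = (int(a) - 1,) if b is None else (int(a) - 1, int(b) - 1)
        comps.append(ElementaryModel(kind, loci))
    return CombinedModel(tuple(comps))
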