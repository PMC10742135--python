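"""Core domain objects for bulk TCR-repertoire classification.

The unit of analysis is the *clonotype*: the collection of receptors that
share a V segment, a J segment and a CDR3 amino-acid sequence.  A
:class:`Repertoire` is the clonotype table of one sample for one chain
(TRA or TRB), carrying the diagnostic label (coeliac disease or control)
and the dietary status (gluten-containing or gluten-free) used downstream.
A :class:`SequenceCatalog` holds published gluten-specific CDR3 sequences,
which form the candidate feature set of the classifier, and a
:class:`PredictiveModel` is a trained decision rule: a chain selection, a
ranked-frequency threshold and the selected coeliac-predictive sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
CHAINS = ("TRA", "TRB")
LABELS = ("CeD", "control", "unknown")
DIETS = ("gluten_containing", "gluten_free", "unknown")


def is_productive(cdr3_aa: str) -> bool:
    """True if ``cdr3_aa`` is a non-empty string over the 20-letter amino-acid
    alphabet (no ``*`` stop codons, no ``_`` frameshift markers)."""
    return bool(cdr3_aa) and set(cdr3_aa) <= AA_ALPHABET


@dataclass(frozen=True)
class Clonotype:
    """A (V segment, J segment, CDR3 amino acid) record with a read count."""

    v_segment: str
    j_segment: str
    cdr3_aa: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"clonotype count must be >= 1, got {self.count}")
        if not is_productive(self.cdr3_aa):
            raise ValueError(f"unproductive CDR3 {self.cdr3_aa!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_segment, self.j_segment, self.cdr3_aa)


@dataclass
class Repertoire:
    """All clonotypes of one sample for one chain, with sample metadata."""

    sample_id: str
    chain: str
    clones: list[Clonotype]
    label: str = "unknown"
    diet: str = "unknown"

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.diet not in DIETS:
            raise ValueError(f"diet must be one of {DIETS}, got {self.diet!r}")
        keys = [c.key for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate (V, J, CDR3) keys in repertoire {self.sample_id}"
            )
        for c in self.clones:
            if not (
                c.v_segment.startswith(self.chain) and c.j_segment.startswith(self.chain)
            ):
                raise ValueError(
                    f"clone {c.key} does not match chain {self.chain} "
                    f"in repertoire {self.sample_id}"
                )

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clones)

    @property
    def cdr3_set(self) -> frozenset[str]:
        return frozenset(c.cdr3_aa for c in self.clones)


@dataclass
class Cohort:
    """A named collection of repertoires; individuals may contribute one
    repertoire per chain, linked across chains by ``sample_id``."""

    name: str
    repertoires: list[Repertoire]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rep in self.repertoires:
            k = (rep.sample_id, rep.chain)
            if k in seen:
                raise ValueError(f"more than one repertoire for {k}")
            seen.add(k)

    def get(self, sample_id: str, chain: str) -> Optional[Repertoire]:
        for rep in self.repertoires:
            if rep.sample_id == sample_id and rep.chain == chain:
                return rep
        return None

    def sample_ids(self, chains: Optional[Sequence[str]] = None) -> list[str]:
        """Distinct sample ids, in first-appearance order, optionally limited
        to individuals with at least one repertoire among ``chains``."""
        out: list[str] = []
        for rep in self.repertoires:
            if chains is not None and rep.chain not in chains:
                continue
            if rep.sample_id not in out:
                out.append(rep.sample_id)
        return out

    def labels(self) -> dict[str, str]:
        """sample_id -> label; chains of one individual must agree."""
        out: dict[str, str] = {}
        for rep in self.repertoires:
            prev = out.setdefault(rep.sample_id, rep.label)
            if prev != rep.label:
                raise ValueError(
                    f"conflicting labels for sample {rep.sample_id}: {prev}/{rep.label}"
                )
        return out

    def diets(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rep in self.repertoires:
            prev = out.setdefault(rep.sample_id, rep.diet)
            if prev != rep.diet:
                raise ValueError(
                    f"conflicting diets for sample {rep.sample_id}: {prev}/{rep.diet}"
                )
        return out

    def subset(self, sample_ids: Iterable[str], name: Optional[str] = None) -> "Cohort":
        wanted = set(sample_ids)
        return Cohort(
            name=name or self.name,
            repertoires=[r for r in self.repertoires if r.sample_id in wanted],
        )


@dataclass(frozen=True)
class CatalogEntry:
    """One published gluten-specific CDR3 with its provenance."""

    chain: str
    cdr3_aa: str
    source_studies: tuple[str, ...] = ()
    epitopes: tuple[str, ...] = ()
    paired: bool = False

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"catalog chain must be TRA or TRB, got {self.chain!r}")
        if not is_productive(self.cdr3_aa):
            raise ValueError(f"invalid catalog CDR3 {self.cdr3_aa!r}")


@dataclass
class SequenceCatalog:
    """Deduplicated set of published gluten-specific CDR3 entries."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        keys = [(e.chain, e.cdr3_aa) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, cdr3_aa) pairs in catalog")

    def sequences(self, chain: str) -> list[str]:
        """CDR3 sequences for one chain, in entry order."""
        return [e.cdr3_aa for e in self.entries if e.chain == chain]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PredictiveModel:
    """A trained decision rule: classify a sample as CeD iff at least one
    coeliac-predictive sequence has ranked frequency <= threshold."""

    chains: tuple[str, ...]
    threshold: float
    sequences: Mapping[str, tuple[str, ...]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chains = tuple(self.chains)
        for ch in self.chains:
            if ch not in CHAINS:
                raise ValueError(f"model chain {ch!r} invalid")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        self.sequences = {
            ch: tuple(sorted(self.sequences.get(ch, ()))) for ch in self.chains
        }


@dataclass
class EvaluationResult:
    """Confusion counts with derived classification measures.

    A measure whose denominator is zero (a class absent from the truth) is
    reported as ``None``.  ``ci`` optionally maps measure name to a
    (lower, upper) 95% bootstrap confidence interval.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    ci: Optional[dict[str, tuple[float, float]]] = None

    @property
    def sensitivity(self) -> Optional[float]:
        p = self.tp + self.fn
        return self.tp / p if p else None

    @property
    def specificity(self) -> Optional[float]:
        n = self.tn + self.fp
        return self.tn / n if n else None

    @property
    def accuracy(self) -> Optional[float]:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else None

    @property
    def balanced_accuracy(self) -> Optional[float]:
        s, sp = self.sensitivity, self.specificity
        if s is None or sp is None:
            return None
        return (s + sp) / 2.0

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }
        if self.ci:
            for k, (lo, hi) in self.ci.items():
                d[f"{k}_ci_low"] = lo
                d[f"{k}_ci_high"] = hi
        return d


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0

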