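"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Each sample is a heavy-tailed background repertoire (Zipf-distributed clone
sizes, random CDR3s kept disjoint from the catalog) into which catalog
sequences are spiked at controlled ranked frequencies: CeD samples carry
planted gluten-specific sequences ranked at or below ``planted_rank_ceiling``
(more in gluten-containing than gluten-free patients), while controls carry
only occasional low-ranked decoy occurrences at or above
``decoy_rank_floor``.  For every threshold t with ceiling <= t < floor the
planted sequences are therefore exactly the selectable set, which is the
parameter-recovery surface used by the tests.

Background clone counts follow a Zipf rank-frequency law with lognormal
jitter, plus a strictly decreasing rank offset (count_i = z_(i) + N - i),
so counts are pairwise distinct and
any rank position can be hit exactly by an integer spike count; without the
offset, the count-1 tail of a pure Zipf draw makes precise placement
impossible because rank inside a tie block is governed by the lexicographic
tie-break, not by abundance.  All sampling goes through a seeded numpy
Generator, so output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .types import CatalogEntry, Clonotype, Cohort, Repertoire, SequenceCatalog

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_BYTES = np.frombuffer(_AA.encode(), dtype=np.uint8)

# epitope labels cycled through synthetic catalog entries
_EPITOPES = (
    "DQ2.5-glia-a1a", "DQ2.5-glia-a2", "DQ2.5-glia-o1", "DQ2.5-glia-o2",
    "DQ2.5-glia-g2", "DQ2.5-hor-3", "DQ8-glia-a1", "DQ8-glia-g1b",
    "DQ2.2-glut-L1",
)

def _default_v_pools() -> dict[str, list[str]]:
    return {
        "TRA": [f"TRAV{i}" for i in range(1, 41)],
        "TRB": [f"TRBV{i}" for i in range(1, 31)],
    }


def _default_j_pools() -> dict[str, list[str]]:
    return {
        "TRA": [f"TRAJ{i}" for i in range(1, 51)],
        "TRB": [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)],
    }


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Sample counts mirror the training cohort (12 CeD of whom 5 are on a
    gluten-free diet, 8 controls); per-diet planting targets mirror the
    reported medians of unique gluten-specific sequences per sample
    (TRA 14 gluten-containing / 2 gluten-free, TRB 9 / 1); clone numbers
    per sample span the reported per-sample clone range.
    """

    n_ced_gcd: int = 7
    n_ced_gfd: int = 5
    n_controls: int = 8
    chains: tuple[str, ...] = ("TRA", "TRB")
    clones_per_sample: tuple[int, int] = (800, 16000)
    zipf_exponent: float = 1.2
    cdr3_length_range: tuple[int, int] = (8, 18)
    v_pools: dict[str, list[str]] = field(default_factory=_default_v_pools)
    j_pools: dict[str, list[str]] = field(default_factory=_default_j_pools)
    catalog_size: dict[str, int] = field(
        default_factory=lambda: {"TRA": 357, "TRB": 799}
    )
    pool_size: dict[str, int] = field(
        default_factory=lambda: {"TRA": 44, "TRB": 28}
    )
    n_shared_core: int = 2
    planted_per_gcd: dict[str, float] = field(
        default_factory=lambda: {"TRA": 14, "TRB": 9}
    )
    planted_per_gfd: dict[str, float] = field(
        default_factory=lambda: {"TRA": 2, "TRB": 1}
    )
    planted_rank_ceiling: float = 0.5
    control_decoy_rate: float = 0.1
    decoy_rank_floor: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.planted_rank_ceiling < self.decoy_rank_floor <= 1.0):
            raise ValueError("need 0 < planted_rank_ceiling < decoy_rank_floor <= 1")
        if min(self.n_ced_gcd, self.n_ced_gfd, self.n_controls) < 0:
            raise ValueError("sample counts must be >= 0")
        for ch in self.chains:
            if self.pool_size[ch] > self.catalog_size[ch]:
                raise ValueError(f"pool_size exceeds catalog_size for {ch}")
            if self.n_shared_core > self.pool_size[ch]:
                raise ValueError("n_shared_core exceeds pool_size")


@dataclass
class GroundTruth:
    """What was planted where: the oracle for parameter-recovery tests."""

    planted: dict[str, frozenset[str]]  # chain -> union of planted sequences
    placements: dict[tuple[str, str], list[tuple[str, float]]]  # (sample, chain)
    decoys: dict[tuple[str, str], list[tuple[str, float]]]
    labels: dict[str, str]
    diets: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "planted": {ch: sorted(s) for ch, s in self.planted.items()},
            "placements": {
                f"{sid}\t{ch}": sorted(pl) for (sid, ch), pl in self.placements.items()
            },
            "decoys": {
                f"{sid}\t{ch}": sorted(pl) for (sid, ch), pl in self.decoys.items()
            },
            "labels": self.labels,
            "diets": self.diets,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _random_cdr3s(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    forbidden: frozenset[str],
) -> list[str]:
    """n distinct random CDR3s, disjoint from ``forbidden``."""
    out: list[str] = []
    seen: set[str] = set()
    lo, hi = length_range
    while len(out) < n:
        todo = n - len(out)
        lengths = rng.integers(lo, hi + 1, size=todo)
        letters = _AA_BYTES[rng.integers(0, 20, size=int(lengths.sum()))]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        for k in range(todo):
            s = letters[offsets[k]:offsets[k + 1]].tobytes().decode()
            if s in seen or s in forbidden:
                continue
            seen.add(s)
            out.append(s)
    return out


def _zipf_counts(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Strictly decreasing clone counts following a Zipf rank-frequency law.

    The i-th largest clone size is (n/i)**exponent with multiplicative
    lognormal jitter, re-sorted and floored at 1, plus a descending rank
    offset that makes counts pairwise distinct (see module docstring).  A
    larger exponent concentrates reads into the top clones.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    base = (n / ranks) ** exponent
    jitter = np.exp(rng.normal(0.0, 0.35, size=n))
    z = np.maximum(np.round(base * jitter), 1.0)
    z = np.sort(z)[::-1].astype(np.int64)
    return z + np.arange(n, 0, -1, dtype=np.int64) - 1


def generate_background_repertoire(
    config: SyntheticConfig,
    sample_id: str,
    chain: str,
    rng: np.random.Generator,
    forbidden: frozenset[str] = frozenset(),
    label: str = "unknown",
    diet: str = "unknown",
) -> Repertoire:
    """One background repertoire: Zipf clone sizes, random CDR3s disjoint
    from ``forbidden`` (the catalog), V/J labels drawn from the pools."""
    lo, hi = config.clones_per_sample
    n = int(rng.integers(lo, hi + 1))
    counts = _zipf_counts(rng, n, config.zipf_exponent)
    cdr3s = _random_cdr3s(rng, n, config.cdr3_length_range, forbidden)
    vs = rng.integers(0, len(config.v_pools[chain]), size=n)
    js = rng.integers(0, len(config.j_pools[chain]), size=n)
    clones = [
        Clonotype(
            v_segment=config.v_pools[chain][vs[i]],
            j_segment=config.j_pools[chain][js[i]],
            cdr3_aa=cdr3s[i],
            count=int(counts[i]),
        )
        for i in range(n)
    ]
    return Repertoire(
        sample_id=sample_id, chain=chain, clones=clones, label=label, diet=diet
    )


def spike_catalog_sequences(
    rep: Repertoire, placements: Sequence[tuple[str, float]]
) -> Repertoire:
    """Insert catalog sequences so each realised ranked frequency lands
    within one rank position (1/N') of its target.

    Background clones are preserved.  Placement counts are chosen against
    the sorted background counts; when the two neighbouring background
    counts differ by exactly one (no integer strictly between), the planted
    clone ties with the lower neighbour and the lexicographic tie-break
    moves it by at most one rank.  A target outside (0, 1] raises an error
    naming the placement.
    """
    if not placements:
        return rep
    for seq, r in placements:
        if not (0.0 < r <= 1.0):
            raise ValueError(f"unattainable target r={r} for placement {seq!r}")
    b = np.sort(np.array([c.count for c in rep.clones], dtype=np.int64))[::-1]
    n = len(b)
    n_final = n + len(placements)
    targeted = sorted(
        ((max(1, min(n_final, round(r * n_final))), seq) for seq, r in placements),
    )
    # resolve position collisions so each planted clone aims at its own rank
    for j in range(1, len(targeted)):
        if targeted[j][0] <= targeted[j - 1][0]:
            targeted[j] = (targeted[j - 1][0] + 1, targeted[j][1])
    overflow = targeted[-1][0] - n_final if targeted else 0
    if overflow > 0:  # shift the trailing run back inside [1, n_final]
        targeted = [(min(p, n_final - (len(targeted) - 1 - k)), s)
                    for k, (p, s) in enumerate(targeted)]
    new_clones = list(rep.clones)
    chain = rep.chain
    for j, (pos, seq) in enumerate(targeted):
        n_before_bg = pos - 1 - j
        if n_before_bg <= 0:
            count = int(b[0]) + 1 if n else 1
        elif n_before_bg >= n:
            count = max(1, int(b[-1]) - 1)
        else:
            upper, lower = int(b[n_before_bg - 1]), int(b[n_before_bg])
            count = lower + 1 if upper - lower >= 2 else lower
        new_clones.append(
            Clonotype(
                v_segment=f"{chain}V1",
                j_segment=f"{chain}J1",
                cdr3_aa=seq,
                count=count,
            )
        )
    return Repertoire(
        sample_id=rep.sample_id,
        chain=chain,
        clones=new_clones,
        label=rep.label,
        diet=rep.diet,
    )


def _make_catalog(config: SyntheticConfig, rng: np.random.Generator) -> SequenceCatalog:
    entries: list[CatalogEntry] = []
    for ch in config.chains:
        seqs = _random_cdr3s(
            rng, config.catalog_size[ch], config.cdr3_length_range, frozenset()
        )
        for i, s in enumerate(seqs):
            entries.append(
                CatalogEntry(
                    chain=ch,
                    cdr3_aa=s,
                    source_studies=(f"synthetic-study-{i % 16 + 1}",),
                    epitopes=(_EPITOPES[i % len(_EPITOPES)],),
                    paired=False,
                )
            )
    return SequenceCatalog(entries=entries)


def generate_cohort(
    config: SyntheticConfig,
    name: str = "synthetic",
    catalog: Optional[SequenceCatalog] = None,
) -> tuple[Cohort, SequenceCatalog, GroundTruth]:
    """Generate a labelled cohort, its catalog and the ground truth.

    CeD samples receive planted catalog sequences (drawn from a per-chain
    planted pool that includes ``n_shared_core`` sequences common to every
    CeD sample, guaranteeing cross-sample sharing) at ranked frequencies
    below the ceiling; controls receive decoy occurrences above the floor.
    Passing the ``catalog`` of a previously generated cohort (with a new
    config seed) produces an independent testing cohort whose planted
    sequences come from the same published feature set.  Fully
    deterministic for a fixed config seed.
    """
    root = np.random.SeedSequence(config.seed)
    cat_ss, samples_ss = root.spawn(2)
    if catalog is None:
        catalog = _make_catalog(config, np.random.default_rng(cat_ss))
    else:
        for ch in config.chains:
            if len(catalog.sequences(ch)) < config.catalog_size[ch]:
                raise ValueError(f"supplied catalog too small for chain {ch}")
    pools = {ch: catalog.sequences(ch)[: config.pool_size[ch]] for ch in config.chains}
    cores = {ch: pools[ch][: config.n_shared_core] for ch in config.chains}

    samples: list[tuple[str, str, str]] = []  # (sample_id, label, diet)
    for i in range(config.n_ced_gcd):
        samples.append((f"CeD_GCD_{i + 1:02d}", "CeD", "gluten_containing"))
    for i in range(config.n_ced_gfd):
        samples.append((f"CeD_GFD_{i + 1:02d}", "CeD", "gluten_free"))
    for i in range(config.n_controls):
        samples.append((f"CTRL_{i + 1:02d}", "control", "unknown"))

    streams = samples_ss.spawn(len(samples) * len(config.chains))
    reps: list[Repertoire] = []
    placements: dict[tuple[str, str], list[tuple[str, float]]] = {}
    decoys: dict[tuple[str, str], list[tuple[str, float]]] = {}
    planted: dict[str, set[str]] = {ch: set() for ch in config.chains}
    k = 0
    for sid, label, diet in samples:
        for ch in config.chains:
            rng = np.random.default_rng(streams[k])
            k += 1
            forbidden = frozenset(catalog.sequences(ch))
            rep = generate_background_repertoire(
                config, sid, ch, rng, forbidden=forbidden, label=label, diet=diet
            )
            place: list[tuple[str, float]] = []
            if label == "CeD":
                target = (
                    config.planted_per_gcd[ch]
                    if diet == "gluten_containing"
                    else config.planted_per_gfd[ch]
                )
                n_plant = int(max(config.n_shared_core, rng.poisson(target)))
                n_plant = min(n_plant, config.pool_size[ch])
                chosen = list(cores[ch])
                extra = [s for s in pools[ch] if s not in cores[ch]]
                n_extra = n_plant - len(chosen)
                if n_extra > 0:
                    picks = rng.choice(len(extra), size=n_extra, replace=False)
                    chosen += [extra[int(p)] for p in picks]
                ceiling = config.planted_rank_ceiling
                for seq in chosen:
                    r = float(rng.uniform(0.02, ceiling - 0.01))
                    place.append((seq, r))
                planted[ch].update(chosen)
                placements[(sid, ch)] = place
            else:
                floor = config.decoy_rank_floor
                dec: list[tuple[str, float]] = []
                hit = rng.random(len(forbidden)) < config.control_decoy_rate
                for seq, h in zip(sorted(forbidden), hit):
                    if h:
                        r = float(rng.uniform(floor + 0.01, 0.995))
                        dec.append((seq, r))
                place = dec
                decoys[(sid, ch)] = dec
            reps.append(spike_catalog_sequences(rep, place))
    truth = GroundTruth(
        planted={ch: frozenset(planted[ch]) for ch in config.chains},
        placements=placements,
        decoys=decoys,
        labels={sid: label for sid, label, _ in samples},
        diets={sid: diet for sid, _, diet in samples},
    )
    return Cohort(name=name, repertoires=reps), catalog, truth


def write_cohort(
    cohort: Cohort,
    catalog: SequenceCatalog,
    truth: Optional[GroundTruth],
    outdir: rio.PathLike,
) -> Path:
    """Write a cohort as AIRR-dialect TSVs with a manifest, the catalog TSV
    and (when given) the ground-truth JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in cohort.repertoires:
        fname = f"{rep.sample_id}.{rep.chain}.airr.tsv"
        rio.write_repertoire(rep, outdir / fname)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "chain": rep.chain,
                "label": rep.label,
                "diet": rep.diet,
                "path": fname,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=rio.MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False
    )
    rio.write_catalog(catalog, outdir / "catalog.tsv")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return manifest
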