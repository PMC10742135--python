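import hypothesis
import numpy as np
import pytest

from ced_tcr import Clonotype, Cohort, Repertoire, SequenceCatalog, CatalogEntry
from ced_tcr.simulate import SyntheticConfig, generate_cohort

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")

# compact generator settings used by most tests: the cohort layout, catalog
# separation (ceiling 0.5 / floor 0.8) and planting structure are the study
# conditions; only per-sample clone numbers are reduced for fast unit tests
FAST_CFG = dict(
    clones_per_sample=(300, 800),
    catalog_size={"TRA": 50, "TRB": 50},
    pool_size={"TRA": 20, "TRB": 15},
    seed=3,
)


@pytest.fixture(scope="session")
def planted():
    """A fast seeded planted cohort: (cohort, catalog, ground_truth)."""
    return generate_cohort(SyntheticConfig(**FAST_CFG))


def make_repertoire(records, sample_id="s1", chain="TRB", label="unknown",
                    diet="unknown"):
    """records: list of (cdr3, count) or (cdr3, count, v, j)."""
    clones = []
    for rec in records:
        if len(rec) == 2:
            cdr3, count = rec
            v, j = f"{chain}V1", f"{chain}J1"
        else:
            cdr3, count, v, j = rec
        clones.append(Clonotype(v_segment=v, j_segment=j, cdr3_aa=cdr3, count=count))
    return Repertoire(sample_id=sample_id, chain=chain, clones=clones,
                      label=label, diet=diet)


def make_catalog(seqs, chain="TRB"):
    return SequenceCatalog(entries=[CatalogEntry(chain=chain, cdr3_aa=s)
                                    for s in seqs])


def oracle_ranked_frequency(rep, cdr3):
    """Independent literal computation of a CDR3's minimum ranked frequency:
    enumerate clones sorted by descending count with the lexicographic tie
    rule and take the smallest i/N over clones carrying the CDR3."""
    ordered = sorted(
        rep.clones,
        key=lambda c: (-c.count, c.cdr3_aa, c.v_segment, c.j_segment),
    )
    n = len(ordered)
    best = None
    for i, c in enumerate(ordered, start=1):
        if c.cdr3_aa == cdr3:
            r = i / n
            if best is None or r < best:
                best = r
    return best


def oracle_select(cohort, catalog, t, chain):
    """Brute-force enumeration of the coeliac-predictive rule: for every
    (catalog sequence, sample) pair check presence at r <= t; keep sequences
    with >= 1 CeD hit and zero control hits."""
    selected = set()
    for seq in catalog.sequences(chain):
        ced_hit = ctrl_hit = False
        for rep in cohort.repertoires:
            if rep.chain != chain or rep.n_clones == 0:
                continue
            r = oracle_ranked_frequency(rep, seq)
            hit = r is not None and r <= t + 1e-12
            if rep.label == "CeD" and hit:
                ced_hit = True
            if rep.label == "control" and hit:
                ctrl_hit = True
        if ced_hit and not ctrl_hit:
            selected.add(seq)
    return frozenset(selected)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_instance(rng, max_samples=10, max_catalog=50):
    """A random small labelled cohort sharing a small CDR3 universe with a
    random catalog, so catalog hits, ties and control occurrences all occur."""
    universe = [
        "".join(rng.choice(list(AA20), size=rng.integers(4, 8)))
        for _ in range(rng.integers(8, 25))
    ]
    n_samples = int(rng.integers(2, max_samples + 1))
    reps = []
    labels = ["CeD", "control"] + [
        str(rng.choice(["CeD", "control"])) for _ in range(n_samples - 2)
    ]
    for i in range(n_samples):
        n_clones = int(rng.integers(1, 12))
        picks = rng.choice(len(universe), size=n_clones, replace=False) \
            if n_clones <= len(universe) else rng.integers(0, len(universe), n_clones)
        clones = {}
        for k, p in enumerate(picks):
            key = (f"TRBV{int(rng.integers(1, 4))}", f"TRBJ{int(rng.integers(1, 3))}",
                   universe[int(p)])
            clones[key] = clones.get(key, 0) + int(rng.integers(1, 6))
        reps.append(
            Repertoire(
                sample_id=f"s{i}", chain="TRB",
                clones=[Clonotype(v_segment=v, j_segment=j, cdr3_aa=c, count=n)
                        for (v, j, c), n in clones.items()],
                label=labels[i],
            )
        )
    n_cat = int(rng.integers(1, min(max_catalog, len(universe)) + 1))
    cat_seqs = [universe[int(p)]
                for p in rng.choice(len(universe), size=n_cat, replace=False)]
    return (
        Cohort(name="rand", repertoires=reps),
        make_catalog(cat_seqs, chain="TRB"),
    )
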