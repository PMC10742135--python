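"""Readers and writers for clonotype tables, sequence catalogs and models.

Two clonotype-table dialects are supported:

* ``mixcr`` — the tab-separated clonotype export of MiXCR's
  ``analyze amplicon`` workflow (columns ``cloneCount``,
  ``bestVHit``/``allVHitsWithScore``, ``bestJHit``/``allJHitsWithScore``,
  ``aaSeqCDR3``);
* ``airr`` — the AIRR Rearrangement standard TSV (columns
  ``duplicate_count``, ``v_call``, ``j_call``, ``junction_aa``).

On read, unproductive records (CDR3 outside the 20-letter amino-acid
alphabet) are dropped, allele suffixes (``*01``) and alignment-score
annotations are stripped from segment names so usage aggregates at the gene
level, and records sharing a (V, J, CDR3) key are merged with counts summed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .types import (
    CHAINS,
    CatalogEntry,
    Clonotype,
    Cohort,
    PredictiveModel,
    Repertoire,
    SequenceCatalog,
    is_productive,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MANIFEST_COLUMNS = ["sample_id", "chain", "label", "diet", "path"]
CATALOG_COLUMNS = ["chain", "cdr3_aa", "source_study", "epitopes", "paired"]

_DIALECTS = {
    "mixcr": {"count": "cloneCount", "v": ("bestVHit", "allVHitsWithScore"),
              "j": ("bestJHit", "allJHitsWithScore"), "cdr3": "aaSeqCDR3"},
    "airr": {"count": "duplicate_count", "v": ("v_call",), "j": ("j_call",),
             "cdr3": "junction_aa"},
}


class TableFormatError(ValueError):
    """A required column is missing or a field value cannot be interpreted."""


def strip_segment_name(raw: str) -> str:
    """Reduce a segment annotation to its gene name.

    Multi-hit fields keep the first (best-scoring) hit; score annotations in
    parentheses and allele suffixes after ``*`` are removed:
    ``"TRBV19*00(1250),TRBV19-1*00(900)"`` -> ``"TRBV19"``.
    """
    first = raw.split(",")[0].strip()
    return first.split("(")[0].split("*")[0].strip()


def read_clonotype_table(
    path: PathLike,
    dialect: str,
    *,
    sample_id: str,
    chain: str,
    label: str = "unknown",
    diet: str = "unknown",
) -> Repertoire:
    """Parse one clonotype table into a validated :class:`Repertoire`.

    Raises :class:`TableFormatError` naming the missing column when the
    dialect's required columns are absent.  An input that is empty after the
    productivity filter yields an empty repertoire with a logged warning.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected mixcr or airr")
    spec = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)

    missing = []
    if spec["count"] not in df.columns:
        missing.append(spec["count"])
    v_col = next((c for c in spec["v"] if c in df.columns), None)
    if v_col is None:
        missing.append(spec["v"][0])
    j_col = next((c for c in spec["j"] if c in df.columns), None)
    if j_col is None:
        missing.append(spec["j"][0])
    if spec["cdr3"] not in df.columns:
        missing.append(spec["cdr3"])
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) for dialect {dialect}: "
            + ", ".join(missing)
        )

    merged: dict[tuple[str, str, str], int] = {}
    n_unproductive = n_wrong_chain = n_bad_count = 0
    for raw_count, raw_v, raw_j, raw_cdr3 in zip(
        df[spec["count"]], df[v_col], df[j_col], df[spec["cdr3"]]
    ):
        if pd.isna(raw_cdr3) or pd.isna(raw_v) or pd.isna(raw_j) or pd.isna(raw_count):
            n_unproductive += 1
            continue
        cdr3 = str(raw_cdr3).strip()
        if not is_productive(cdr3):
            n_unproductive += 1
            continue
        try:
            count = int(round(float(raw_count)))
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: cannot parse count value {raw_count!r}"
            ) from exc
        if count < 1:
            n_bad_count += 1
            continue
        v = strip_segment_name(str(raw_v))
        j = strip_segment_name(str(raw_j))
        if not (v.startswith(chain) and j.startswith(chain)):
            n_wrong_chain += 1
            continue
        key = (v, j, cdr3)
        merged[key] = merged.get(key, 0) + count

    if n_wrong_chain:
        logger.warning(
            "%s: dropped %d record(s) whose segments do not match chain %s",
            path, n_wrong_chain, chain,
        )
    clones = [
        Clonotype(v_segment=v, j_segment=j, cdr3_aa=c, count=n)
        for (v, j, c), n in merged.items()
    ]
    if not clones:
        logger.warning("%s: no productive records; returning empty repertoire", path)
    return Repertoire(
        sample_id=sample_id, chain=chain, clones=clones, label=label, diet=diet
    )


def write_repertoire(rep: Repertoire, path: PathLike) -> None:
    """Write a repertoire as an AIRR-dialect TSV (the canonical on-disk form)."""
    df = pd.DataFrame(
        {
            "duplicate_count": [c.count for c in rep.clones],
            "v_call": [c.v_segment for c in rep.clones],
            "j_call": [c.j_segment for c in rep.clones],
            "junction_aa": [c.cdr3_aa for c in rep.clones],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: PathLike) -> SequenceCatalog:
    """Load the curated gluten-specific sequence catalog.

    Entries are deduplicated on (chain, cdr3_aa); provenance of duplicates is
    merged (all source studies and epitopes retained, ``paired`` true if any
    duplicate was paired).  An unknown chain value is a format error: only
    TRA and TRB sequences are considered.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: catalog missing required column(s): " + ", ".join(missing)
        )
    merged: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        chain = str(row["chain"]).strip()
        if chain not in CHAINS:
            raise TableFormatError(
                f"{path}: unknown chain {chain!r}; only TRA and TRB are accepted"
            )
        cdr3 = str(row["cdr3_aa"]).strip()
        if not is_productive(cdr3):
            raise TableFormatError(f"{path}: invalid catalog CDR3 {cdr3!r}")
        sources = [] if pd.isna(row["source_study"]) else [str(row["source_study"])]
        epitopes = (
            []
            if pd.isna(row["epitopes"]) or not str(row["epitopes"]).strip()
            else [e for e in str(row["epitopes"]).split(";") if e]
        )
        paired = str(row["paired"]).strip().lower() in ("true", "1", "yes")
        key = (chain, cdr3)
        if key not in merged:
            merged[key] = {"sources": [], "epitopes": [], "paired": False}
            order.append(key)
        rec = merged[key]
        rec["sources"].extend(s for s in sources if s not in rec["sources"])
        rec["epitopes"].extend(e for e in epitopes if e not in rec["epitopes"])
        rec["paired"] = rec["paired"] or paired
    entries = [
        CatalogEntry(
            chain=chain,
            cdr3_aa=cdr3,
            source_studies=tuple(merged[(chain, cdr3)]["sources"]),
            epitopes=tuple(merged[(chain, cdr3)]["epitopes"]),
            paired=merged[(chain, cdr3)]["paired"],
        )
        for chain, cdr3 in order
    ]
    return SequenceCatalog(entries=entries)


def write_catalog(catalog: SequenceCatalog, path: PathLike) -> None:
    rows = [
        {
            "chain": e.chain,
            "cdr3_aa": e.cdr3_aa,
            "source_study": "|".join(e.source_studies),
            "epitopes": ";".join(e.epitopes),
            "paired": str(e.paired),
        }
        for e in catalog.entries
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort(
    manifest_path: PathLike, dialect: str, name: Optional[str] = None
) -> Cohort:
    """Read a cohort through its manifest TSV
    (columns sample_id, chain, label, diet, path; paths relative to the
    manifest's directory)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{manifest_path}: manifest missing column(s): " + ", ".join(missing)
        )
    reps = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        reps.append(
            read_clonotype_table(
                p,
                dialect,
                sample_id=row["sample_id"],
                chain=row["chain"],
                label=row["label"],
                diet=row["diet"],
            )
        )
    return Cohort(name=name or manifest_path.stem, repertoires=reps)


def save_model(model: PredictiveModel, path: PathLike) -> None:
    """Serialize a trained model to JSON (round-trip safe)."""
    from . import __version__

    payload = {
        "chains": list(model.chains),
        "threshold": model.threshold,
        "sequences": {ch: list(model.sequences[ch]) for ch in model.chains},
        "metadata": model.metadata,
        "tool_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: PathLike) -> PredictiveModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TableFormatError(f"{path}: malformed model file: {exc}") from exc
    for key in ("chains", "threshold", "sequences"):
        if key not in payload:
            raise TableFormatError(f"{path}: model file missing key {key!r}")
    return PredictiveModel(
        chains=tuple(payload["chains"]),
        threshold=float(payload["threshold"]),
        sequences={ch: tuple(seqs) for ch, seqs in payload["sequences"].items()},
        metadata=payload.get("metadata", {}),
    )
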