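"""Annotation overlay for co-regulation screen results.

Joins screened PsOPs with externally supplied annotation tables — binary
interactors (BioGRID/IntAct-style exports), predicted upstream kinases
and downstream substrates (pre-computed NetworKIN/AKID/kinome-atlas-style
exports, optionally filtered at a percentile-score cut-off) and pathway
gene sets — and compares the passing PsOP sets of two anchors.

Annotations never alter screen statistics: the join only attaches
annotation sources to otherwise unchanged screen rows.  Matching is by
gene symbol (gene-level tables) or (symbol, position) (site-level
tables); no fuzzy matching is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .coreg import CoregResult, passing_sites, screen_to_frame

ANNOTATION_KINDS = ("interactor", "kinase", "substrate", "gene_set")


class AnnotationError(ValueError):
    """Raised for malformed annotation tables."""


@dataclass
class AnnotationTable:
    """A validated annotation table of one kind.

    ``entries`` has columns ``symbol``, ``position`` (nullable Int64),
    ``source`` and ``score`` (nullable float), plus ``set_name`` for
    gene-set tables.  ``site_specific`` is True when every entry carries a
    position.
    """

    kind: str
    entries: pd.DataFrame
    site_specific: bool = False

    def __len__(self) -> int:
        return len(self.entries)


def load_annotations(
    paths: Sequence[str | Path] | str | Path,
    kind: str,
    *,
    min_percentile: float | None = None,
) -> AnnotationTable:
    """Load and validate annotation TSVs of one kind.

    Expected columns: ``symbol [position] source [score]`` (gene sets:
    ``set_name symbol``).  Duplicate entries are de-duplicated with their
    source labels merged (``;``-joined).  ``min_percentile`` drops rows
    whose percentile ``score`` falls below the cut-off (e.g. 90 keeps only
    predictions at or above the 90th percentile).
    """
    if kind not in ANNOTATION_KINDS:
        raise AnnotationError(f"unknown annotation kind {kind!r}")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        if df.empty:
            warnings.warn(f"annotation file {p} is empty", stacklevel=2)
            continue
        frames.append(df)
    if not frames:
        cols = ["set_name", "symbol"] if kind == "gene_set" else ["symbol", "position", "source", "score"]
        return AnnotationTable(kind=kind, entries=pd.DataFrame(columns=cols))
    raw = pd.concat(frames, ignore_index=True)

    if kind == "gene_set":
        for col in ("set_name", "symbol"):
            if col not in raw.columns:
                raise AnnotationError(f"gene-set table missing required column {col!r}")
        entries = raw[["set_name", "symbol"]].drop_duplicates().reset_index(drop=True)
        return AnnotationTable(kind=kind, entries=entries)

    if "symbol" not in raw.columns:
        raise AnnotationError("annotation table missing required column 'symbol'")
    if "source" not in raw.columns:
        raw["source"] = kind
    has_position = "position" in raw.columns
    if has_position:
        blank = raw["position"].astype(str).str.strip() == ""
        if blank.any() and not blank.all():
            raise AnnotationError(
                f"site-specific rows without a position at indices {raw.index[blank].tolist()[:10]}"
            )
        site_specific = not blank.all()
    else:
        raw["position"] = ""
        site_specific = False

    entries = pd.DataFrame(
        {
            "symbol": raw["symbol"].str.strip(),
            "position": pd.to_numeric(raw["position"].replace("", pd.NA), errors="raise").astype("Int64"),
            "source": raw["source"],
            "score": pd.to_numeric(raw.get("score", pd.Series("", index=raw.index)).replace("", pd.NA), errors="coerce"),
        }
    )
    if min_percentile is not None:
        if entries["score"].isna().all():
            raise AnnotationError("percentile filtering requested but table has no score column")
        entries = entries[entries["score"] >= min_percentile]

    entries = (
        entries.groupby(["symbol", "position"], dropna=False, as_index=False)
        .agg(source=("source", lambda s: ";".join(sorted(set(s)))), score=("score", "max"))
        .reset_index(drop=True)
    )
    return AnnotationTable(kind=kind, entries=entries, site_specific=site_specific)


def annotate_screen(
    results: list[CoregResult],
    tables: Sequence[AnnotationTable],
    *,
    level: Literal["gene", "site"] = "gene",
    passing_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join screen results with annotation tables.

    Gene-level matching joins on the PsOP's gene symbol; ``level="site"``
    additionally requires the annotation's position to equal the PsOP's
    position for site-specific tables.  Returns the annotated table (screen
    columns byte-identical to :func:`~phosphocoreg.coreg.screen_to_frame`
    output, plus ``annotation_kind`` and ``annotation_source``) and
    per-kind match counts over distinct PsOPs.
    """
    base = screen_to_frame(results)
    if passing_only:
        base = base[base["passes"]].reset_index(drop=True)
    base = base.assign(
        _symbol=base["other"].str.rsplit("_", n=1).str[0],
        _position=base["other"].str.rsplit("_", n=1).str[1].str[1:].astype(int),
    )
    annotated_parts = []
    counts: dict[str, int] = {}
    for table in tables:
        if table.kind == "gene_set":
            ann = table.entries.rename(columns={"symbol": "_symbol"})
            ann = ann.assign(annotation_kind=table.kind, annotation_source=ann.pop("set_name"))
            hit = base.merge(ann, on="_symbol", how="inner")
        else:
            ann = table.entries.rename(columns={"symbol": "_symbol", "position": "_ann_position"})
            ann = ann.assign(annotation_kind=table.kind, annotation_source=ann.pop("source"))
            hit = base.merge(ann, on="_symbol", how="inner")
            if level == "site" and table.site_specific:
                hit = hit[hit["_ann_position"].astype("Int64") == hit["_position"]]
            hit = hit.drop(columns=["_ann_position", "score"], errors="ignore")
        counts[table.kind] = counts.get(table.kind, 0) + hit["other"].nunique()
        annotated_parts.append(hit)
    if annotated_parts:
        out = pd.concat(annotated_parts, ignore_index=True)
    else:
        out = base.iloc[0:0].assign(annotation_kind=pd.Series(dtype=str), annotation_source=pd.Series(dtype=str))
    out = out.drop(columns=["_symbol", "_position"]).reset_index(drop=True)
    return out, counts


@dataclass
class AnchorComparison:
    """Shared and exclusive passing PsOPs of two anchor screens."""

    anchor_a: str
    anchor_b: str
    shared: list[str]
    exclusive_a: list[str]
    exclusive_b: list[str]

    def summary(self) -> dict:
        return {
            "anchor_a": self.anchor_a,
            "anchor_b": self.anchor_b,
            "n_shared": len(self.shared),
            "n_exclusive_a": len(self.exclusive_a),
            "n_exclusive_b": len(self.exclusive_b),
            "shared": self.shared,
        }


def compare_anchors(
    screen_a: list[CoregResult],
    screen_b: list[CoregResult],
    *,
    direction: Literal["positive", "negative"] = "positive",
) -> AnchorComparison:
    """Overlap of the passing PsOP sets of two anchors (deterministic order)."""
    a_sites = {s.label for s in passing_sites(screen_a, direction)}
    b_sites = {s.label for s in passing_sites(screen_b, direction)}
    name_a = screen_a[0].tally.anchor.label if screen_a else "anchor_a"
    name_b = screen_b[0].tally.anchor.label if screen_b else "anchor_b"
    return AnchorComparison(
        anchor_a=name_a,
        anchor_b=name_b,
        shared=sorted(a_sites & b_sites),
        exclusive_a=sorted(a_sites - b_sites),
        exclusive_b=sorted(b_sites - a_sites),
    )
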