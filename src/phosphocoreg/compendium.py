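"""Phosphoproteomic dataset compendium: data model, I/O and regulation calling.

A *compendium* is a collection of phosphoproteomic datasets of two kinds:

* **profiling** datasets — qualitative detection lists; a phosphosite either
  appears (``DETECTED``) or it does not;
* **differential** datasets — quantitative test-vs-control comparisons where
  each observed site carries a fold change and (usually) a p-value, and is
  called ``UP``, ``DOWN`` or ``NS`` (not significant).

Every dataset belongs to a study (PMID) and carries a condition code
describing the biological/experimental condition, which downstream screens
use as replication evidence.

The on-disk format is UTF-8 TSV with the header::

    dataset_id  pmid  condition_code  kind  gene_symbol  uniprot_acc
    residue  position  fold_change  p_value

with empty strings for absent numeric fields (profiling rows have no fold
change; some differential sources ship without p-values).
"""

from __future__ import annotations

import enum
import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phosphocoreg")

PHOSPHO_RESIDUES = frozenset("STY")

#: Documented TSV columns, in order.
COMPENDIUM_COLUMNS = [
    "dataset_id",
    "pmid",
    "condition_code",
    "kind",
    "gene_symbol",
    "uniprot_acc",
    "residue",
    "position",
    "fold_change",
    "p_value",
]

_SITE_LABEL_RE = re.compile(r"^(?P<symbol>[A-Za-z0-9][A-Za-z0-9\-]*)_(?P<residue>[STY])(?P<position>\d+)$")


class Call(str, enum.Enum):
    """Regulation call for one phosphosite observation in one dataset."""

    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"
    DETECTED = "DETECTED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CompendiumError(ValueError):
    """Raised for format or invariant violations in compendium tables."""


@dataclass(frozen=True, order=True)
class SiteID:
    """A phosphosite: gene symbol, accession, 1-based position and residue.

    Rendered as ``SYMBOL_<residue><position>``, e.g. ``TNIK_S640``.
    Positions refer to the canonical protein sequence; isoform coordinates
    must be remapped upstream (see the ``mapping`` argument of
    :func:`read_compendium`).
    """

    gene_symbol: str
    position: int
    residue: str
    uniprot_acc: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")

    @property
    def label(self) -> str:
        return f"{self.gene_symbol}_{self.residue}{self.position}"

    def __str__(self) -> str:
        return self.label

    @classmethod
    def parse(cls, label: str, uniprot_acc: str = "") -> "SiteID":
        """Parse a ``SYMBOL_S640``-style label."""
        m = _SITE_LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"not a valid site label: {label!r}")
        return cls(
            gene_symbol=m.group("symbol"),
            position=int(m.group("position")),
            residue=m.group("residue"),
            uniprot_acc=uniprot_acc,
        )


@dataclass(frozen=True)
class DatasetMeta:
    """Metadata of one dataset: id, study (PMID), condition code and kind."""

    dataset_id: str
    pmid: str
    condition_code: str
    kind: Literal["profiling", "differential"]

    def __post_init__(self) -> None:
        if self.kind not in ("profiling", "differential"):
            raise ValueError(f"kind must be 'profiling' or 'differential', got {self.kind!r}")


@dataclass(frozen=True)
class Observation:
    """One phosphosite measurement in one dataset with its regulation call."""

    site: SiteID
    dataset_id: str
    call: Call
    fold_change: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class Thresholds:
    """Regulation-calling and high-confidence screen thresholds.

    Attributes
    ----------
    up_fc, down_fc
        Fold-change cut-offs: a differential observation is UP if
        ``fold_change >= up_fc`` and DOWN if ``fold_change <= down_fc``
        (boundaries inclusive), in both cases requiring ``p_value < alpha``.
    alpha
        Significance level for the per-observation p-value (strict ``<``).
    predominance_fraction
        A site is *predominant* when its dataset fraction strictly exceeds
        this value.
    hc_ratio, hc_min_pmids, hc_min_codes, hc_fet_alpha
        The four high-confidence co-regulation criteria: support ratio
        (inclusive ``>=``), minimum distinct studies, minimum distinct
        condition codes, and the Fisher-exact p cut-off (strict ``<``).
    """

    up_fc: float = 1.3
    down_fc: float = 0.76
    alpha: float = 0.05
    predominance_fraction: float = 0.5
    hc_ratio: float = 0.10
    hc_min_pmids: int = 3
    hc_min_codes: int = 3
    hc_fet_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.down_fc < 1.0 < self.up_fc):
            raise ValueError("thresholds must satisfy down_fc < 1 < up_fc")
        for name in ("alpha", "predominance_fraction", "hc_ratio", "hc_fet_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        """Load thresholds from a flat YAML mapping; unknown keys rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise CompendiumError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


DEFAULT_THRESHOLDS = Thresholds()


def classify_observation(
    fold_change: float,
    p_value: float | None,
    th: Thresholds = DEFAULT_THRESHOLDS,
    *,
    trust_prefiltered: bool = False,
) -> Call:
    """Call one differential observation UP, DOWN or NS.

    UP requires ``fold_change >= th.up_fc`` and ``p_value < th.alpha``;
    DOWN requires ``fold_change <= th.down_fc`` and ``p_value < th.alpha``.
    Fold-change boundaries are inclusive, the p-value cut-off is strict.

    A missing p-value yields NS unless ``trust_prefiltered`` is set, in
    which case the source dataset is assumed to ship already-significant
    rows and the fold change alone decides.
    """
    if not (fold_change > 0) or math.isnan(fold_change):
        raise ValueError(f"fold change must be positive, got {fold_change}")
    if p_value is None or (isinstance(p_value, float) and math.isnan(p_value)):
        significant = trust_prefiltered
    else:
        if not (0.0 < p_value <= 1.0):
            raise ValueError(f"p-value must lie in (0, 1], got {p_value}")
        significant = p_value < th.alpha
    if significant and fold_change >= th.up_fc:
        return Call.UP
    if significant and fold_change <= th.down_fc:
        return Call.DOWN
    return Call.NS


@dataclass
class Compendium:
    """A validated collection of datasets and phosphosite observations.

    ``datasets`` is a DataFrame indexed by ``dataset_id`` with columns
    ``pmid``, ``condition_code`` and ``kind``.  ``observations`` is a
    DataFrame with one row per (site, dataset) and columns ``dataset_id``,
    ``gene_symbol``, ``uniprot_acc``, ``residue``, ``position``,
    ``fold_change``, ``p_value`` and the computed ``call``.
    """

    datasets: pd.DataFrame
    observations: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def differential_ids(self) -> list[str]:
        return list(self.datasets.index[self.datasets["kind"] == "differential"])

    @property
    def profiling_ids(self) -> list[str]:
        return list(self.datasets.index[self.datasets["kind"] == "profiling"])

    def site_label_column(self) -> pd.Series:
        obs = self.observations
        return (
            obs["gene_symbol"].astype(str)
            + "_"
            + obs["residue"].astype(str)
            + obs["position"].astype(int).astype(str)
        )

    def sites(self) -> list[SiteID]:
        """Distinct sites in the compendium, sorted by label."""
        obs = self.observations.drop_duplicates(
            subset=["gene_symbol", "residue", "position"]
        )
        out = [
            SiteID(r.gene_symbol, int(r.position), r.residue, r.uniprot_acc)
            for r in obs.itertuples()
        ]
        return sorted(out, key=lambda s: s.label)


def _validate_observation_frame(obs: pd.DataFrame, datasets: pd.DataFrame) -> None:
    bad_res = ~obs["residue"].isin(sorted(PHOSPHO_RESIDUES))
    if bad_res.any():
        rows = obs.index[bad_res].tolist()[:10]
        raise CompendiumError(f"invalid residue (must be S/T/Y) at rows {rows}")
    bad_pos = obs["position"] < 1
    if bad_pos.any():
        raise CompendiumError(f"non-positive site positions at rows {obs.index[bad_pos].tolist()[:10]}")
    unknown = ~obs["dataset_id"].isin(datasets.index)
    if unknown.any():
        ids = sorted(obs.loc[unknown, "dataset_id"].unique())
        raise CompendiumError(f"observations reference unknown dataset ids: {ids[:10]}")


def _collapse_duplicates(obs: pd.DataFrame) -> pd.DataFrame:
    # multiple peptides covering one site in one dataset: keep the row with
    # the most extreme |log fold change|; profiling duplicates collapse to one
    key = ["dataset_id", "gene_symbol", "residue", "position"]
    extremeness = np.abs(np.log(obs["fold_change"].astype(float))).fillna(0.0)
    order = extremeness.sort_values(ascending=False).index
    collapsed = obs.loc[order].drop_duplicates(subset=key, keep="first")
    n_dropped = len(obs) - len(collapsed)
    if n_dropped:
        logger.info("collapsed %d duplicate (site, dataset) observations", n_dropped)
    return collapsed.sort_index()


def read_compendium(
    paths: Sequence[str | Path] | str | Path,
    mapping: pd.DataFrame | str | Path | None = None,
    th: Thresholds = DEFAULT_THRESHOLDS,
    *,
    on_duplicate: Literal["error", "collapse"] = "error",
    trust_prefiltered: bool = False,
) -> Compendium:
    """Read one or more compendium TSV tables into a validated :class:`Compendium`.

    Parameters
    ----------
    paths
        TSV file(s) with the documented columns (:data:`COMPENDIUM_COLUMNS`).
    mapping
        Optional symbol/accession remap table with columns
        ``old_symbol new_symbol [new_acc]`` (frozen HGNC snapshot; the
        package never queries a live service).
    on_duplicate
        ``"error"`` (default) rejects duplicated (site, dataset) rows with a
        listing of offenders; ``"collapse"`` keeps the most extreme
        |log fold change| per (site, dataset).
    trust_prefiltered
        Treat differential rows with a beyond-threshold fold change but no
        p-value as already significant (opt-in; default calls them NS).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in COMPENDIUM_COLUMNS if c not in df.columns]
        if missing:
            raise CompendiumError(f"{p}: missing required column(s) {missing}")
        frames.append(df[COMPENDIUM_COLUMNS])
    raw = pd.concat(frames, ignore_index=True)

    bad_kind = ~raw["kind"].isin(["profiling", "differential"])
    if bad_kind.any():
        raise CompendiumError(
            f"invalid dataset kind at rows {raw.index[bad_kind].tolist()[:10]} "
            "(must be 'profiling' or 'differential')"
        )

    if mapping is not None:
        if isinstance(mapping, (str, Path)):
            mapping = pd.read_csv(mapping, sep="\t", dtype=str)
        remap = dict(zip(mapping["old_symbol"], mapping["new_symbol"]))
        raw["gene_symbol"] = raw["gene_symbol"].map(lambda s: remap.get(s, s))
        if "new_acc" in mapping.columns:
            acc_map = dict(zip(mapping["old_symbol"], mapping["new_acc"]))
            # remap accessions keyed on the pre-remap symbol
            old_symbols = pd.concat(frames, ignore_index=True)["gene_symbol"]
            raw["uniprot_acc"] = [
                acc_map.get(old, acc) for old, acc in zip(old_symbols, raw["uniprot_acc"])
            ]

    datasets = (
        raw[["dataset_id", "pmid", "condition_code", "kind"]]
        .drop_duplicates()
        .set_index("dataset_id")
    )
    if datasets.index.has_duplicates:
        dup = sorted(datasets.index[datasets.index.duplicated()].unique())
        raise CompendiumError(
            f"dataset ids with conflicting metadata (pmid/code/kind must be fixed per dataset): {dup}"
        )

    obs = raw[["dataset_id", "gene_symbol", "uniprot_acc", "residue", "position"]].copy()
    obs["position"] = pd.to_numeric(raw["position"], errors="raise").astype(int)
    obs["fold_change"] = pd.to_numeric(raw["fold_change"].replace("", np.nan), errors="raise")
    obs["p_value"] = pd.to_numeric(raw["p_value"].replace("", np.nan), errors="raise")
    _validate_observation_frame(obs, datasets)

    key = ["dataset_id", "gene_symbol", "residue", "position"]
    dup_mask = obs.duplicated(subset=key, keep=False)
    if dup_mask.any():
        if on_duplicate == "error":
            offenders = (
                obs.loc[dup_mask, key]
                .drop_duplicates()
                .apply(lambda r: f"{r.gene_symbol}_{r.residue}{r.position}@{r.dataset_id}", axis=1)
                .tolist()
            )
            raise CompendiumError(f"duplicate (site, dataset) observations: {offenders[:10]}")
        obs = _collapse_duplicates(obs)

    obs = obs.reset_index(drop=True)
    obs["call"] = _call_column(obs, datasets, th, trust_prefiltered=trust_prefiltered)
    return Compendium(datasets=datasets, observations=obs, thresholds=th)


def _call_column(
    obs: pd.DataFrame,
    datasets: pd.DataFrame,
    th: Thresholds,
    *,
    trust_prefiltered: bool = False,
) -> pd.Series:
    kind = obs["dataset_id"].map(datasets["kind"])
    calls = pd.Series(Call.DETECTED.value, index=obs.index, dtype=object)
    diff = kind == "differential"
    if diff.any():
        fc = obs.loc[diff, "fold_change"]
        if fc.isna().any():
            raise CompendiumError(
                "differential observations require a fold change; missing at rows "
                f"{fc.index[fc.isna()].tolist()[:10]}"
            )
        pv = obs.loc[diff, "p_value"]
        calls.loc[diff] = [
            classify_observation(f, None if pd.isna(p) else p, th, trust_prefiltered=trust_prefiltered).value
            for f, p in zip(fc, pv)
        ]
    prof = ~diff
    if (obs.loc[prof, "fold_change"].notna()).any():
        raise CompendiumError("profiling observations must not carry a fold change")
    return calls


def write_compendium(c: Compendium, path: str | Path) -> None:
    """Write a compendium back to the documented TSV format (round-trip safe)."""
    obs = c.observations
    out = pd.DataFrame(
        {
            "dataset_id": obs["dataset_id"],
            "pmid": obs["dataset_id"].map(c.datasets["pmid"]),
            "condition_code": obs["dataset_id"].map(c.datasets["condition_code"]),
            "kind": obs["dataset_id"].map(c.datasets["kind"]),
            "gene_symbol": obs["gene_symbol"],
            "uniprot_acc": obs["uniprot_acc"],
            "residue": obs["residue"],
            "position": obs["position"],
            "fold_change": obs["fold_change"],
            "p_value": obs["p_value"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def site_frequencies(c: Compendium, protein: str) -> pd.DataFrame:
    """Per-site dataset counts for one protein.

    Returns a DataFrame indexed by site label with columns ``gene_symbol``,
    ``residue``, ``position``, ``profiling_count``, ``up_count``,
    ``down_count`` and ``differential_count``.  Counts are numbers of
    distinct datasets; ``differential_count`` counts datasets where the site
    is called UP or DOWN (NS does not count).
    """
    obs = c.observations[c.observations["gene_symbol"] == protein]
    if obs.empty:
        warnings.warn(f"protein {protein!r} not present in compendium", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "gene_symbol",
                "residue",
                "position",
                "profiling_count",
                "up_count",
                "down_count",
                "differential_count",
            ]
        )
    key = ["gene_symbol", "residue", "position"]

    def _nuniq(mask: pd.Series) -> pd.Series:
        sub = obs[mask]
        return sub.groupby(key)["dataset_id"].nunique()

    all_sites = obs[key].drop_duplicates().set_index(key).index
    prof = _nuniq(obs["call"] == Call.DETECTED.value)
    up = _nuniq(obs["call"] == Call.UP.value)
    down = _nuniq(obs["call"] == Call.DOWN.value)
    table = pd.DataFrame(
        {"profiling_count": prof, "up_count": up, "down_count": down}, index=all_sites
    )
    table = table.fillna(0).astype(int).reset_index()
    table["differential_count"] = table["up_count"] + table["down_count"]
    table.index = pd.Index(
        table["gene_symbol"] + "_" + table["residue"] + table["position"].astype(str),
        name="site",
    )
    return table.sort_values("position")


def predominant_sites(
    freqs: pd.DataFrame,
    denominator: int,
    th: Thresholds = DEFAULT_THRESHOLDS,
    *,
    count_column: str = "differential_count",
) -> list[SiteID]:
    """Sites whose dataset fraction strictly exceeds the predominance cut-off.

    ``count_column / denominator > th.predominance_fraction`` (strict, i.e.
    "more than 50%" at the default).  Result is ranked by descending count,
    ties broken by ascending position.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if freqs.empty:
        return []
    frac = freqs[count_column] / denominator
    hits = freqs[frac > th.predominance_fraction]
    hits = hits.sort_values([count_column, "position"], ascending=[False, True])
    return [
        SiteID(r.gene_symbol, int(r.position), r.residue)
        for r in hits.itertuples()
    ]


def predominant_sites_for_protein(
    c: Compendium,
    protein: str,
    th: Thresholds = DEFAULT_THRESHOLDS,
    *,
    universe: Literal["differential", "profiling", "both"] = "differential",
) -> list[SiteID]:
    """Detect predominant sites of a protein against a dataset universe.

    The denominator is the number of datasets of the chosen universe in
    which *any* site of the protein was observed; the numerator counts
    differential regulation (``differential``, default), detection
    (``profiling``) or their sum (``both``).
    """
    freqs = site_frequencies(c, protein)
    if freqs.empty:
        return []
    obs = c.observations[c.observations["gene_symbol"] == protein]
    kinds = obs["dataset_id"].map(c.datasets["kind"])
    n_diff = obs.loc[kinds == "differential", "dataset_id"].nunique()
    n_prof = obs.loc[kinds == "profiling", "dataset_id"].nunique()
    freqs = freqs.copy()
    freqs["combined_count"] = freqs["differential_count"] + freqs["profiling_count"]
    if universe == "differential":
        denom, col = n_diff, "differential_count"
    elif universe == "profiling":
        denom, col = n_prof, "profiling_count"
    elif universe == "both":
        denom, col = n_diff + n_prof, "combined_count"
    else:
        raise ValueError(f"unknown predominance universe {universe!r}")
    if denom < 1:
        return []
    return predominant_sites(freqs, denom, th, count_column=col)
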