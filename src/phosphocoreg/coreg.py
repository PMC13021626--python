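"""Anchor-vs-PsOP co-regulation screen.

For an *anchor* phosphosite and every phosphosite on another protein
(PsOP), each differential dataset in which both sites carry an UP or DOWN
call contributes to exactly one of four categories:

====  ==========================  =======================
code  anchor / PsOP direction     interpretation
====  ==========================  =======================
UU    up / up                     positive co-regulation
UD    up / down                   negative co-regulation
DU    down / up                   negative co-regulation
DD    down / down                 positive co-regulation
====  ==========================  =======================

Significance of directional association is assessed with a one-sided
Fisher's exact test on the 2x2 table ``[[nUU, nUD], [nDU, nDD]]`` — the
``greater`` tail for concordance (positive co-regulation), the ``less``
tail for discordance.  A pair is *high-confidence* when it meets four
criteria: FET p below ``hc_fet_alpha`` (strict), support ratio at least
``hc_ratio`` (inclusive), and concordant (resp. discordant) evidence from
at least ``hc_min_pmids`` distinct studies and ``hc_min_codes`` distinct
condition codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .compendium import Call, Compendium, SiteID, Thresholds, DEFAULT_THRESHOLDS

_CRITERIA = ("fet", "ratio", "pmids", "codes")


@dataclass
class PairTally:
    """Directional evidence counts for one anchor/PsOP pair."""

    anchor: SiteID
    other: SiteID
    nUU: int = 0
    nUD: int = 0
    nDU: int = 0
    nDD: int = 0
    pmids_concordant: set[str] = field(default_factory=set)
    pmids_discordant: set[str] = field(default_factory=set)
    codes_concordant: set[str] = field(default_factory=set)
    codes_discordant: set[str] = field(default_factory=set)
    anchor_diff_total: int = 0

    @property
    def table(self) -> list[list[int]]:
        return [[self.nUU, self.nUD], [self.nDU, self.nDD]]

    @property
    def n_codifferential(self) -> int:
        return self.nUU + self.nUD + self.nDU + self.nDD

    def support(self, direction: Literal["positive", "negative"]) -> int:
        if direction == "positive":
            return self.nUU + self.nDD
        return self.nUD + self.nDU


@dataclass
class CoregResult:
    """One screened PsOP in one direction with its filter outcome."""

    tally: PairTally
    direction: Literal["positive", "negative"]
    support: int
    ratio: float
    fet_p: float
    n_pmids: int
    n_codes: int
    passes: bool
    flags: dict[str, bool]
    ambiguous: bool = False

    @property
    def other(self) -> SiteID:
        return self.tally.other


def tally_pair(c: Compendium, anchor: SiteID, other: SiteID) -> PairTally:
    """Tally UU/UD/DU/DD counts for one site pair across differential datasets.

    A dataset contributes iff both sites carry a call in {UP, DOWN} there;
    NS or absent observations exclude it.  PMID and condition-code sets are
    collected from contributing datasets, split by concordance.
    """
    t = PairTally(anchor=anchor, other=other)
    obs = c.observations
    lab = c.site_label_column()
    a_obs = obs[(lab == anchor.label) & obs["call"].isin([Call.UP.value, Call.DOWN.value])]
    t.anchor_diff_total = a_obs["dataset_id"].nunique()
    if t.anchor_diff_total == 0:
        warnings.warn(f"anchor {anchor.label} is differential in no dataset", stacklevel=2)
        return t
    b_obs = obs[(lab == other.label) & obs["call"].isin([Call.UP.value, Call.DOWN.value])]
    a_call = dict(zip(a_obs["dataset_id"], a_obs["call"]))
    for ds, b_call in zip(b_obs["dataset_id"], b_obs["call"]):
        a = a_call.get(ds)
        if a is None:
            continue
        pmid = c.datasets.loc[ds, "pmid"]
        code = c.datasets.loc[ds, "condition_code"]
        if a == Call.UP.value and b_call == Call.UP.value:
            t.nUU += 1
        elif a == Call.UP.value and b_call == Call.DOWN.value:
            t.nUD += 1
        elif a == Call.DOWN.value and b_call == Call.UP.value:
            t.nDU += 1
        else:
            t.nDD += 1
        if a == b_call:
            t.pmids_concordant.add(pmid)
            t.codes_concordant.add(code)
        else:
            t.pmids_discordant.add(pmid)
            t.codes_discordant.add(code)
    return t


def fet_pvalue(t: PairTally, direction: Literal["positive", "negative"]) -> float:
    """One-sided Fisher exact p for the 2x2 table [[nUU, nUD], [nDU, nDD]].

    ``direction="positive"`` tests enrichment of concordant directions
    (odds ratio > 1, ``greater`` tail); ``"negative"`` tests discordance
    (``less`` tail).  The all-zero table carries no information and yields
    p = 1.
    """
    if min(t.nUU, t.nUD, t.nDU, t.nDD) < 0:
        raise ValueError("tally counts must be non-negative")
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    alternative = "greater" if direction == "positive" else "less"
    return float(fisher_exact(t.table, alternative=alternative).pvalue)


def high_confidence(res: CoregResult, th: Thresholds = DEFAULT_THRESHOLDS) -> tuple[bool, dict[str, bool]]:
    """Evaluate the four high-confidence criteria for one screen result.

    Passes iff ``fet_p < th.hc_fet_alpha`` and ``ratio >= th.hc_ratio`` and
    ``n_pmids >= th.hc_min_pmids`` and ``n_codes >= th.hc_min_codes``.
    Returns the overall verdict plus per-criterion flags.
    """
    flags = {
        "fet": res.fet_p < th.hc_fet_alpha,
        "ratio": res.ratio >= th.hc_ratio,
        "pmids": res.n_pmids >= th.hc_min_pmids,
        "codes": res.n_codes >= th.hc_min_codes,
    }
    return all(flags.values()), flags


def _differential_matrix(c: Compendium) -> tuple[pd.Index, np.ndarray, list[str]]:
    """Site x dataset direction matrix over differential datasets (+1 UP, -1 DOWN, 0 else)."""
    obs = c.observations
    diff_ids = c.differential_ids
    lab = c.site_label_column()
    mask = obs["call"].isin([Call.UP.value, Call.DOWN.value])
    sub = pd.DataFrame(
        {
            "site": lab[mask],
            "dataset_id": obs.loc[mask, "dataset_id"],
            "dir": np.where(obs.loc[mask, "call"] == Call.UP.value, 1, -1).astype(np.int8),
        }
    )
    mat = (
        sub.pivot_table(index="site", columns="dataset_id", values="dir", aggfunc="first", fill_value=0)
        .reindex(columns=diff_ids, fill_value=0)
    )
    return mat.index, mat.to_numpy(dtype=np.int8), diff_ids


def coregulation_screen(
    c: Compendium,
    anchor: SiteID,
    th: Thresholds = DEFAULT_THRESHOLDS,
    *,
    ratio_denominator: Literal["anchor", "compendium"] = "anchor",
    restrict_to: set[str] | None = None,
) -> list[CoregResult]:
    """Screen every PsOP against the anchor and apply the four criteria.

    Emits one :class:`CoregResult` per (PsOP, direction) with support > 0,
    ordered by descending support, then ascending p, then site label.
    A site can pass in at most one direction — the one with strictly larger
    support; equal support in both directions marks both rows ambiguous and
    neither passes.  Sites on the anchor's own protein are excluded.

    ``ratio_denominator`` selects the support-ratio denominator: datasets
    where the anchor itself is differential (default) or all differential
    datasets of the compendium.
    """
    sites_idx, M, diff_ids = _differential_matrix(c)
    if anchor.label not in sites_idx:
        warnings.warn(f"anchor {anchor.label} is differential in no dataset", stacklevel=2)
        return []
    a_row = M[sites_idx.get_loc(anchor.label)]
    anchor_cols = a_row != 0
    anchor_diff_total = int(anchor_cols.sum())
    denom = anchor_diff_total if ratio_denominator == "anchor" else len(diff_ids)
    if ratio_denominator not in ("anchor", "compendium"):
        raise ValueError(f"unknown ratio_denominator {ratio_denominator!r}")

    ds_sub = [d for d, keep in zip(diff_ids, anchor_cols) if keep]
    pmid_sub = c.datasets.loc[ds_sub, "pmid"].to_numpy()
    code_sub = c.datasets.loc[ds_sub, "condition_code"].to_numpy()
    a_sub = a_row[anchor_cols]
    M_sub = M[:, anchor_cols]

    up_a = a_sub == 1
    results: list[CoregResult] = []
    site_meta = {s.label: s for s in c.sites()}
    for i, label in enumerate(sites_idx):
        site = site_meta[label]
        if site.gene_symbol == anchor.gene_symbol:
            continue
        if restrict_to is not None and label not in restrict_to:
            continue
        row = M_sub[i]
        present = row != 0
        if not present.any():
            continue
        conc = present & (row == a_sub)
        disc = present & (row == -a_sub)
        t = PairTally(
            anchor=anchor,
            other=site,
            nUU=int((conc & up_a).sum()),
            nDD=int((conc & ~up_a).sum()),
            nUD=int((disc & up_a).sum()),
            nDU=int((disc & ~up_a).sum()),
            pmids_concordant=set(pmid_sub[conc]),
            pmids_discordant=set(pmid_sub[disc]),
            codes_concordant=set(code_sub[conc]),
            codes_discordant=set(code_sub[disc]),
            anchor_diff_total=anchor_diff_total,
        )
        s_pos, s_neg = t.support("positive"), t.support("negative")
        ambiguous = s_pos == s_neg and s_pos > 0
        for direction, supp in (("positive", s_pos), ("negative", s_neg)):
            if supp == 0:
                continue
            res = CoregResult(
                tally=t,
                direction=direction,  # type: ignore[arg-type]
                support=supp,
                ratio=supp / denom if denom else 0.0,
                fet_p=fet_pvalue(t, direction),  # type: ignore[arg-type]
                n_pmids=len(t.pmids_concordant if direction == "positive" else t.pmids_discordant),
                n_codes=len(t.codes_concordant if direction == "positive" else t.codes_discordant),
                passes=False,
                flags={},
                ambiguous=ambiguous,
            )
            ok, flags = high_confidence(res, th)
            dominant = supp > (s_neg if direction == "positive" else s_pos)
            res.passes = ok and dominant and not ambiguous
            res.flags = flags | {"dominant_direction": dominant}
            results.append(res)

    results.sort(key=lambda r: (-r.support, r.fet_p, r.other.label, r.direction))
    return results


def screen_to_frame(results: list[CoregResult], *, fdr: bool = False) -> pd.DataFrame:
    """Tabulate screen results in the documented TSV column layout.

    With ``fdr=True`` an extra Benjamini–Hochberg ``fet_q`` column is
    appended (an extension — the high-confidence criteria themselves use
    raw FET p-values only).
    """
    rows = []
    for r in results:
        t = r.tally
        rows.append(
            {
                "anchor": t.anchor.label,
                "other": r.other.label,
                "direction": r.direction,
                "nUU": t.nUU,
                "nUD": t.nUD,
                "nDU": t.nDU,
                "nDD": t.nDD,
                "support": r.support,
                "ratio": r.ratio,
                "fet_p": r.fet_p,
                "n_pmids": r.n_pmids,
                "n_codes": r.n_codes,
                "passes": r.passes,
                "flags": ";".join(k for k, v in r.flags.items() if v) or "-",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "anchor",
            "other",
            "direction",
            "nUU",
            "nUD",
            "nDU",
            "nDD",
            "support",
            "ratio",
            "fet_p",
            "n_pmids",
            "n_codes",
            "passes",
            "flags",
        ],
    )
    if fdr and len(df):
        from scipy.stats import false_discovery_control

        df["fet_q"] = false_discovery_control(df["fet_p"].to_numpy(), method="bh")
    return df


def passing_sites(results: list[CoregResult], direction: Literal["positive", "negative"] = "positive") -> list[SiteID]:
    """Sites that pass the high-confidence screen in the given direction."""
    return sorted(
        (r.other for r in results if r.passes and r.direction == direction),
        key=lambda s: s.label,
    )
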