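"""Intra-protein phosphosite co-occurrence.

For every pair of phosphosites on one protein that are co-differential in
at least one dataset, tallies the directional categories UU/UD/DU/DD
(reusing the pairwise tally of :mod:`phosphocoreg.coreg`) and summarises
them as the positive co-regulation frequency ``(nUU + nDD) / (nUD + nDU)``
and its reciprocal, the negative co-regulation frequency.  A zero
denominator is reported as infinity and flagged rather than clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .compendium import Call, Compendium, SiteID
from .coreg import PairTally, tally_pair


@dataclass
class CooccurrenceRecord:
    """Directional tallies and frequency ratios for one intra-protein pair.

    Sites are canonically ordered: ``site_a.position < site_b.position``.
    """

    site_a: SiteID
    site_b: SiteID
    nUU: int
    nUD: int
    nDU: int
    nDD: int
    pos_freq: float
    neg_freq: float
    pos_undefined: bool = False
    neg_undefined: bool = False


def _ratios(conc: int, disc: int) -> tuple[float, float, bool, bool]:
    pos_undef = disc == 0
    neg_undef = conc == 0
    pos = math.inf if pos_undef else conc / disc
    neg = math.inf if neg_undef else disc / conc
    return pos, neg, pos_undef, neg_undef


def intra_protein_pairs(
    c: Compendium,
    protein: str,
    sites: list[SiteID] | None = None,
) -> list[CooccurrenceRecord]:
    """Co-occurrence records for all differential site pairs of one protein.

    Only pairs sharing at least one co-differential dataset are returned;
    an optional ``sites`` list restricts the pairs considered.  Records are
    ordered by (position_a, position_b).
    """
    obs = c.observations
    mask = (obs["gene_symbol"] == protein) & obs["call"].isin([Call.UP.value, Call.DOWN.value])
    sub = obs[mask].drop_duplicates(subset=["residue", "position"])
    eligible = sorted(
        (SiteID(protein, int(r.position), r.residue, r.uniprot_acc) for r in sub.itertuples()),
        key=lambda s: s.position,
    )
    if sites is not None:
        wanted = {s.label for s in sites}
        eligible = [s for s in eligible if s.label in wanted]
    if len(eligible) < 2:
        warnings.warn(f"fewer than two differential sites for {protein!r}", stacklevel=2)
        return []
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-pair anchor warnings are noise here
        for a, b in combinations(eligible, 2):
            t = tally_pair(c, a, b)
            if t.n_codifferential == 0:
                continue
            pos, neg, pu, nu = _ratios(t.nUU + t.nDD, t.nUD + t.nDU)
            records.append(
                CooccurrenceRecord(
                    site_a=a,
                    site_b=b,
                    nUU=t.nUU,
                    nUD=t.nUD,
                    nDU=t.nDU,
                    nDD=t.nDD,
                    pos_freq=pos,
                    neg_freq=neg,
                    pos_undefined=pu,
                    neg_undefined=nu,
                )
            )
    return records


def cooccurrence_matrix(records: list[CooccurrenceRecord]) -> pd.DataFrame:
    """Square site-by-site matrix: upper triangle positive frequency, lower negative.

    Sites are ordered by position; undefined (infinite) ratios and pairs
    without co-differential evidence are NA.  Raises if the records span
    more than one protein.
    """
    if not records:
        return pd.DataFrame()
    proteins = {r.site_a.gene_symbol for r in records} | {r.site_b.gene_symbol for r in records}
    if len(proteins) > 1:
        raise ValueError(f"records span multiple proteins: {sorted(proteins)}")
    sites = sorted(
        {r.site_a for r in records} | {r.site_b for r in records},
        key=lambda s: s.position,
    )
    labels = [s.label for s in sites]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for r in sorted(records, key=lambda x: (x.site_a.position, x.site_b.position)):
        ia, ib = r.site_a.label, r.site_b.label
        if not math.isinf(r.pos_freq):
            mat.loc[ia, ib] = r.pos_freq
        if not math.isinf(r.neg_freq):
            mat.loc[ib, ia] = r.neg_freq
    return mat


def records_to_frame(records: list[CooccurrenceRecord]) -> pd.DataFrame:
    """Long-form table (`site_a site_b nUU nUD nDU nDD pos_freq neg_freq`)."""
    return pd.DataFrame(
        [
            {
                "site_a": r.site_a.label,
                "site_b": r.site_b.label,
                "nUU": r.nUU,
                "nUD": r.nUD,
                "nDU": r.nDU,
                "nDD": r.nDD,
                "pos_freq": r.pos_freq,
                "neg_freq": r.neg_freq,
            }
            for r in records
        ],
        columns=["site_a", "site_b", "nUU", "nUD", "nDU", "nDD", "pos_freq", "neg_freq"],
    )
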