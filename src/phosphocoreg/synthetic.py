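"""Synthetic compendium generator with planted co-regulation ground truth.

Emulates the statistical structure of a curated phosphoproteomic
compendium around one *anchor* phosphosite: a set of differential datasets
(grouped into studies and condition codes) in which the anchor is
up/down-regulated in a known fraction, together with

* positively coupled sites that follow the anchor's direction with
  probability ``coupling_prob``,
* negatively coupled sites that mirror it with the same probability, and
* independent background sites whose directions are fair coin flips.

Fold changes are drawn from a directional log-normal truncated so that
every generated observation re-classifies to its intended call under the
calling thresholds (UP/DOWN observations get p ~ Uniform(0, alpha), NS
observations a neutral fold change and p ~ Uniform(alpha, 1)); the
generated tables therefore round-trip exactly through
:func:`~phosphocoreg.compendium.classify_observation`.

All randomness flows from a single seed via one named
``numpy.random.Generator`` stream; generation is fully reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium import (
    Call,
    Compendium,
    SiteID,
    Thresholds,
    _call_column,
)


class SyntheticParamError(ValueError):
    """Raised for inconsistent generator parameters."""


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the planted-compendium generator.

    Defaults describe the benchmark condition used throughout the test
    suite: 40 differential datasets from 8 studies under 10 condition
    codes, an anchor differential in 60% of datasets, 30 positively and 30
    negatively coupled sites at coupling probability 0.95, and 270
    independent background sites (330 non-anchor sites in total), each
    detected in 80% of datasets.
    """

    n_datasets: int = 40
    n_studies: int = 8
    n_condition_codes: int = 10
    anchor: SiteID = field(default_factory=lambda: SiteID("TNIK", 640, "S", "Q9UKE5"))
    anchor_diff_fraction: float = 0.6
    n_pos_coupled: int = 30
    n_neg_coupled: int = 30
    n_background: int = 270
    coupling_prob: float = 0.95
    detection_prob: float = 0.8
    fc_log_mean: float = math.log(2.0)
    fc_log_sd: float = 0.35
    n_profiling_datasets: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise SyntheticParamError("n_datasets must be >= 1")
        if not (1 <= self.n_studies <= self.n_datasets):
            raise SyntheticParamError("n_studies must lie in [1, n_datasets]")
        if self.n_condition_codes < 1:
            raise SyntheticParamError("n_condition_codes must be >= 1")
        if not (0.5 <= self.coupling_prob <= 1.0):
            raise SyntheticParamError("coupling_prob must lie in [0.5, 1]")
        for name in ("anchor_diff_fraction", "detection_prob"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise SyntheticParamError(f"{name} must lie in (0, 1]")
        if min(self.n_pos_coupled, self.n_neg_coupled, self.n_background) < 0:
            raise SyntheticParamError("site counts must be non-negative")

    def replace(self, **kwargs) -> "SyntheticParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated compendium.

    The three site sets are disjoint and exclude the anchor;
    ``anchor_direction`` maps each dataset id where the anchor is
    differential to ``"UP"`` or ``"DOWN"``.
    """

    pos_coupled: set[SiteID]
    neg_coupled: set[SiteID]
    background: set[SiteID]
    anchor_direction: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pos_coupled": sorted(s.label for s in self.pos_coupled),
            "neg_coupled": sorted(s.label for s in self.neg_coupled),
            "background": sorted(s.label for s in self.background),
            "anchor_direction": self.anchor_direction,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _site_set(prefix: str, n: int, start_pos: int = 100) -> list[SiteID]:
    return [SiteID(f"{prefix}{i + 1:03d}", start_pos, "S") for i in range(n)]


def _directional_fc(rng: np.random.Generator, up: np.ndarray, p: SyntheticParams, th: Thresholds) -> np.ndarray:
    """Log-normal fold-change magnitudes, truncated beyond the call cut-offs."""
    floor = max(math.log(th.up_fc), -math.log(th.down_fc)) + 1e-9
    mag = rng.normal(p.fc_log_mean, p.fc_log_sd, size=up.shape)
    mag = np.maximum(mag, floor)
    return np.where(up, np.exp(mag), np.exp(-mag))


def _neutral_fc(rng: np.random.Generator, n: int, th: Thresholds) -> np.ndarray:
    lo, hi = math.log(th.down_fc) + 1e-6, math.log(th.up_fc) - 1e-6
    return np.exp(rng.uniform(lo, hi, size=n))


def generate(
    params: SyntheticParams,
    th: Thresholds | None = None,
) -> tuple[Compendium, SyntheticTruth]:
    """Generate a compendium with planted coupling and its ground truth.

    In each differential dataset the anchor is differential with
    probability ``anchor_diff_fraction`` (direction a fair coin, NS
    otherwise).  Every other site is detected with probability
    ``detection_prob``; a detected coupled site follows (positively
    coupled) or mirrors (negatively coupled) the anchor's direction with
    probability ``coupling_prob``, and falls back to a fair coin in
    datasets where the anchor is NS.  Background directions are always
    fair coins.
    """
    params.validate()
    th = th or Thresholds()
    rng = np.random.default_rng(params.seed)

    pos = _site_set("POS", params.n_pos_coupled)
    neg = _site_set("NEG", params.n_neg_coupled)
    bg = _site_set("BG", params.n_background)
    sites = pos + neg + bg
    site_class = ["pos"] * len(pos) + ["neg"] * len(neg) + ["bg"] * len(bg)

    D = params.n_datasets
    dataset_ids = [f"ds{i + 1:03d}" for i in range(D)]
    # studies by contiguous blocks, condition codes round-robin
    block = int(np.ceil(D / params.n_studies))
    pmids = [f"PMID{(i // block) + 1:04d}" for i in range(D)]
    codes = [f"C{(i % params.n_condition_codes) + 1:02d}" for i in range(D)]

    anchor_diff = rng.random(D) < params.anchor_diff_fraction
    anchor_up = rng.random(D) < 0.5  # direction where differential

    rows: list[dict] = []

    def _emit(site: SiteID, ds: str, fc: float, pv: float) -> None:
        rows.append(
            {
                "dataset_id": ds,
                "gene_symbol": site.gene_symbol,
                "uniprot_acc": site.uniprot_acc,
                "residue": site.residue,
                "position": site.position,
                "fold_change": fc,
                "p_value": pv,
            }
        )

    anchor_direction: dict[str, str] = {}
    for d in range(D):
        ds = dataset_ids[d]
        if anchor_diff[d]:
            up = bool(anchor_up[d])
            anchor_direction[ds] = "UP" if up else "DOWN"
            fc = float(_directional_fc(rng, np.array([up]), params, th)[0])
            _emit(params.anchor, ds, fc, float(rng.uniform(0, th.alpha)))
        else:
            _emit(params.anchor, ds, float(_neutral_fc(rng, 1, th)[0]), float(rng.uniform(th.alpha, 1)))

        detected = rng.random(len(sites)) < params.detection_prob
        coupled_follow = rng.random(len(sites)) < params.coupling_prob
        coin = rng.random(len(sites)) < 0.5
        for j, site in enumerate(sites):
            if not detected[j]:
                continue
            if anchor_diff[d] and site_class[j] == "pos":
                up = bool(anchor_up[d]) if coupled_follow[j] else not bool(anchor_up[d])
            elif anchor_diff[d] and site_class[j] == "neg":
                up = (not bool(anchor_up[d])) if coupled_follow[j] else bool(anchor_up[d])
            else:
                up = bool(coin[j])
            fc = float(_directional_fc(rng, np.array([up]), params, th)[0])
            _emit(site, ds, fc, float(rng.uniform(0, th.alpha)))

    meta_rows = [
        {"dataset_id": ds, "pmid": pm, "condition_code": cc, "kind": "differential"}
        for ds, pm, cc in zip(dataset_ids, pmids, codes)
    ]

    for i in range(params.n_profiling_datasets):
        ds = f"pf{i + 1:03d}"
        meta_rows.append(
            {
                "dataset_id": ds,
                "pmid": f"PMIDP{(i % max(params.n_studies, 1)) + 1:03d}",
                "condition_code": f"C{(i % params.n_condition_codes) + 1:02d}",
                "kind": "profiling",
            }
        )
        detected = rng.random(len(sites) + 1) < params.detection_prob
        for j, site in enumerate([params.anchor] + sites):
            if detected[j]:
                _emit(site, ds, np.nan, np.nan)

    datasets = pd.DataFrame(meta_rows).set_index("dataset_id")
    obs = pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "gene_symbol",
            "uniprot_acc",
            "residue",
            "position",
            "fold_change",
            "p_value",
        ],
    )
    obs["position"] = obs["position"].astype(int)
    obs["call"] = _call_column(obs, datasets, th)
    compendium = Compendium(datasets=datasets, observations=obs, thresholds=th)
    truth = SyntheticTruth(
        pos_coupled=set(pos),
        neg_coupled=set(neg),
        background=set(bg),
        anchor_direction=anchor_direction,
    )
    return compendium, truth


def generate_null(
    params: SyntheticParams,
    th: Thresholds | None = None,
) -> tuple[Compendium, SyntheticTruth]:
    """Generate a null compendium: every non-anchor site is background.

    The coupled-site counts of ``params`` are folded into the background
    so the total number of non-anchor sites is preserved; the returned
    truth has empty coupled sets.
    """
    total = params.n_pos_coupled + params.n_neg_coupled + params.n_background
    null_params = params.replace(n_pos_coupled=0, n_neg_coupled=0, n_background=total)
    return generate(null_params, th)
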