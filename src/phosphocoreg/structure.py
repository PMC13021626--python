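"""Structural accessibility of phosphosites on a predicted model.

Given a predicted structure in PDB format (with per-residue pLDDT stored
in the B-factor column, as AlphaFold does), this module computes for each
residue:

* accessible surface area (ASA, Å²) with a rolling-probe algorithm
  (probe radius 1.4 Å),
* relative solvent accessibility ``RSA = ASA / maxASA(residue type)``
  normalised to [0, 1] (Sander–Rost residue maxima by default, Tien 2013
  as an option),
* a binary *loop indicator*: 1 for coil/turn/bend residues, 0 for
  helix/sheet residues, derived from a DSSP-convention secondary-structure
  code,
* normalised pLDDT (``pLDDT / 100``), and
* the composite Phosphosite Accessibility Index

  .. math:: PAI = 0.5 \\cdot RSA_{norm} + 0.3 \\cdot pLDDT_{norm} + 0.2 \\cdot Loop

ASA and secondary structure are computed with biotite (Shrake–Rupley
surface sampling and the P-SEA geometric assigner); the test suite checks
the ASA against an independent Shrake–Rupley implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

#: Residue maximum ASA (Å²), Sander & Rost (1994) — the table used by
#: DSSP-style RSA normalisation.
MAX_ASA_SANDER = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

#: Theoretical maximum ASA (Å²), Tien et al. (2013).
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

MAX_ASA_TABLES = {"sander": MAX_ASA_SANDER, "tien": MAX_ASA_TIEN}

#: DSSP 8-state alphabet -> loop indicator. Helix (H/G/I) and sheet (E)
#: plus isolated beta-bridges (B) are rigid (0); turn, bend, polyproline
#: helix and coil are flexible (1).
LOOP_BY_SS_CODE = {
    "H": 0, "G": 0, "I": 0, "E": 0, "B": 0,
    "T": 1, "S": 1, "P": 1, "-": 1,
}

_SSE_TO_DSSP = {"a": "H", "b": "E", "c": "-"}

PAI_WEIGHTS = (0.5, 0.3, 0.2)


class StructureError(ValueError):
    """Raised for unusable structure files or out-of-range inputs."""


@dataclass
class StructureModel:
    """A single-chain protein model parsed from a PDB file.

    ``residues`` has one row per standard residue with columns
    ``position`` (author residue number), ``residue`` (one-letter code)
    and ``plddt`` (CA B-factor); ``atoms`` keeps the underlying atom array
    for surface and secondary-structure computations.
    """

    residues: pd.DataFrame
    atoms: "struc.AtomArray"
    chain_id: str
    plddt_missing: bool = False

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        return self.residues["position"].to_numpy()


@dataclass
class StructuralSiteProfile:
    """Accessibility profile of one residue: ASA, RSA, loop flag, pLDDT, PAI."""

    position: int
    residue: str
    asa: float
    rsa_norm: float
    ss_code: str
    loop: int
    plddt: float
    plddt_norm: float
    pai: float


def read_model(path, chain: str | None = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only standard amino-acid ATOM records of one chain are retained
    (the first chain by default — AlphaFold models are single-chain).
    The CA atom's B-factor is kept per residue as its pLDDT; an all-zero
    B-factor column flags pLDDT as missing.
    """
    try:
        pdb = PDBFile.read(path)
        array = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    array = array[struc.filter_amino_acids(array)]
    if array.array_length() == 0:
        raise StructureError(f"{path}: no standard amino-acid ATOM records")
    chains = list(dict.fromkeys(array.chain_id))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise StructureError(f"chain {chain!r} not in model (available: {chains})")
    array = array[array.chain_id == chain]

    rows = []
    for res in struc.residue_iter(array):
        three = res.res_name[0]
        try:
            one = struc.info.one_letter_code(three)
        except Exception:
            one = None
        if not one:
            one = "X"
        ca = res[res.atom_name == "CA"]
        bfac = float(ca.b_factor[0]) if ca.array_length() else float(np.mean(res.b_factor))
        rows.append({"position": int(res.res_id[0]), "residue": one.upper(), "plddt": bfac})
    residues = pd.DataFrame(rows)
    if not residues["position"].is_monotonic_increasing:
        residues = residues.sort_values("position").reset_index(drop=True)
    plddt_missing = bool((residues["plddt"] == 0).all())
    return StructureModel(residues=residues, atoms=array, chain_id=chain, plddt_missing=plddt_missing)


def accessibility(
    model: StructureModel,
    *,
    probe_radius: float = 1.4,
    point_number: int = 1000,
    max_asa_table: str = "sander",
) -> pd.DataFrame:
    """Per-residue ASA (Å²) and normalised RSA.

    ASA uses Shrake–Rupley surface-point sampling with the given probe
    radius; RSA divides by the residue-type maximum from the chosen table
    and is clipped to [0, 1] (a free residue can exceed the folded-chain
    maximum).  Residues of unknown type get NaN RSA and are flagged.
    """
    table = MAX_ASA_TABLES[max_asa_table]
    atom_sasa = struc.sasa(
        model.atoms, probe_radius=probe_radius, point_number=point_number, vdw_radii="ProtOr"
    )
    res_asa = struc.apply_residue_wise(model.atoms, atom_sasa, np.nansum)
    out = model.residues[["position", "residue"]].copy()
    out["asa"] = res_asa
    max_asa = out["residue"].map(table)
    out["rsa_norm"] = (out["asa"] / max_asa).clip(0.0, 1.0)
    out["rsa_flag"] = max_asa.isna()
    return out


def secondary_structure(model: StructureModel) -> pd.DataFrame:
    """Per-residue secondary-structure code (DSSP convention) and loop flag.

    Uses biotite's geometric P-SEA assigner; its three states map to
    H (helix), E (sheet) and ``-`` (coil).  The contract downstream is the
    binary loop indicator only.
    """
    sse = struc.annotate_sse(model.atoms)
    out = model.residues[["position", "residue"]].copy()
    codes = [_SSE_TO_DSSP.get(s, "-") for s in sse]
    if len(codes) != len(out):  # e.g. residues without complete backbone
        codes = (codes + ["-"] * len(out))[: len(out)]
    out["ss_code"] = codes
    out["loop"] = [loop_indicator(s) for s in out["ss_code"]]
    return out


def loop_indicator(ss_code: str) -> int:
    """Map a DSSP-convention secondary-structure code to the loop flag.

    Helix (H, G, I), sheet (E) and isolated bridge (B) residues are rigid
    (0); turn (T), bend (S), polyproline (P) and coil (-) are flexible (1).
    """
    try:
        return LOOP_BY_SS_CODE[ss_code]
    except KeyError:
        raise ValueError(f"unknown secondary-structure code {ss_code!r}") from None


def pai(rsa_norm: float, plddt_norm: float, loop: int | float) -> float:
    """Phosphosite Accessibility Index: 0.5*RSA + 0.3*pLDDT/100 + 0.2*loop.

    All inputs must lie in [0, 1]; the weights sum to 1 so the index does
    too.
    """
    for name, v in (("rsa_norm", rsa_norm), ("plddt_norm", plddt_norm), ("loop", loop)):
        if not (0.0 <= v <= 1.0) or np.isnan(v):
            raise StructureError(f"{name} must lie in [0, 1], got {v}")
    w_rsa, w_plddt, w_loop = PAI_WEIGHTS
    return w_rsa * rsa_norm + w_plddt * plddt_norm + w_loop * loop


def profile_all(
    model: StructureModel,
    *,
    max_asa_table: str = "sander",
    point_number: int = 1000,
) -> pd.DataFrame:
    """Full per-residue profile: ``position residue asa rsa_norm ss loop plddt pai``.

    Missing pLDDT (all-zero B-factors) enters the PAI as 0 and is flagged
    in ``plddt_flag`` rather than imputed.
    """
    acc = accessibility(model, max_asa_table=max_asa_table, point_number=point_number)
    ss = secondary_structure(model)
    out = acc.merge(ss[["position", "ss_code", "loop"]], on="position")
    out["plddt"] = model.residues["plddt"].to_numpy()
    out["plddt_flag"] = model.plddt_missing
    out["plddt_norm"] = 0.0 if model.plddt_missing else out["plddt"] / 100.0
    out["pai"] = [
        pai(r, p, l) if not np.isnan(r) else np.nan
        for r, p, l in zip(out["rsa_norm"], out["plddt_norm"], out["loop"])
    ]
    return out


def profile_sites(
    model: StructureModel,
    sites: list[int],
    *,
    max_asa_table: str = "sander",
    point_number: int = 1000,
) -> tuple[list[StructuralSiteProfile], dict[int, str]]:
    """Accessibility profiles for the requested residue positions.

    Positions absent from the model are reported in the error mapping;
    profiles for the remaining positions are still returned, in the
    requested order.
    """
    full = profile_all(model, max_asa_table=max_asa_table, point_number=point_number)
    by_pos = full.set_index("position")
    profiles: list[StructuralSiteProfile] = []
    errors: dict[int, str] = {}
    for pos in sites:
        if pos not in by_pos.index:
            errors[pos] = f"position {pos} not in model (chain {model.chain_id})"
            continue
        row = by_pos.loc[pos]
        profiles.append(
            StructuralSiteProfile(
                position=int(pos),
                residue=str(row["residue"]),
                asa=float(row["asa"]),
                rsa_norm=float(row["rsa_norm"]),
                ss_code=str(row["ss_code"]),
                loop=int(row["loop"]),
                plddt=float(row["plddt"]),
                plddt_norm=float(row["plddt_norm"]),
                pai=float(row["pai"]),
            )
        )
    return profiles, errors


def profiles_to_frame(profiles: list[StructuralSiteProfile]) -> pd.DataFrame:
    """Tabulate site profiles (`position residue asa rsa_norm ss loop plddt pai`)."""
    return pd.DataFrame(
        [
            {
                "position": p.position,
                "residue": p.residue,
                "asa": p.asa,
                "rsa_norm": p.rsa_norm,
                "ss": p.ss_code,
                "loop": p.loop,
                "plddt": p.plddt,
                "pai": p.pai,
            }
            for p in profiles
        ],
        columns=["position", "residue", "asa", "rsa_norm", "ss", "loop", "plddt", "pai"],
    )
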