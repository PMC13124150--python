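"""Structure-based FRET efficiency prediction.

Given a (typically dimeric) structural model, this module

* enumerates the native aromatic donors (Trp/Tyr),
* builds a simplified rotamer ensemble of fluorophore reference points for
  each labeled site (donor or acceptor) by sampling chi dihedrals from a
  small built-in set and rejecting sterically clashing conformers,
* converts ensemble pairs into weighted donor-acceptor distance
  distributions,
* computes transfer efficiencies with the Foerster relation
  ``E = 1 / (1 + (r/R0)^6)``, including the multi-acceptor generalisation
  ``E = sum_a k_a / (1 + sum_a k_a)`` with ``k_a = (R0/r_a)^6`` (the
  standard kinetic treatment of one donor competing between independent
  acceptors), and
* aggregates over all donors of a construct, either allowing cross-subunit
  transfer (``all_donors``) or restricting each donor to the acceptor copy
  in its own chain (``intrasubunit``).

The rotamer treatment is intentionally coarse: conformers come from
``+-60/180`` chi branches, the fluorophore is collapsed to its ring-system
centroid, and a conformer survives iff that centroid keeps a minimum
distance to every heavy atom outside its own residue.  The orientation
factor is taken as absorbed into the supplied R0 values.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import biotite.structure.io.pdbx as pdbxio

from .errors import (
    DegenerateDistanceError,
    EmptyEnsembleError,
    FormatError,
    PrecisionError,
    SiteError,
    StatisticsError,
)

__all__ = [
    "R0_DEFAULTS",
    "DONOR_RESIDUES",
    "StructureModel",
    "SamplingParams",
    "LabelEnsemble",
    "DistanceDistribution",
    "FretPrediction",
    "OriginFit",
    "load_structure",
    "find_native_donors",
    "build_label_ensemble",
    "ensembles_to_pdb",
    "distance_distribution",
    "pair_efficiency",
    "donor_efficiency_multi_acceptor",
    "construct_prediction",
    "correlate_and_fit",
]

#: Foerster radii (Angstrom) per donor type, orientation factor absorbed.
R0_DEFAULTS = {"TRP": 23.5, "TYR": 20.9}
DONOR_RESIDUES = ("TRP", "TYR")

_ENUMERATION_LIMIT = 10_000


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Thin wrapper around a biotite ``AtomArray`` with validated topology."""

    atoms: struc.AtomArray
    source: str = ""

    def __post_init__(self) -> None:
        arr = self.atoms
        if arr.array_length() == 0:
            raise FormatError("structure contains no atoms")
        if not np.all(np.isfinite(arr.coord)):
            raise FormatError("non-finite coordinates in structure")
        for chain in self.chains:
            sub = arr[arr.chain_id == chain]
            ids, names = struc.get_residues(sub)
            if len(ids) != len(set(ids)):
                raise FormatError(f"duplicate residue ids in chain {chain!r}")

    @property
    def chains(self) -> list[str]:
        return [str(c) for c in np.unique(self.atoms.chain_id)]

    def residues(self, chain: str) -> list[tuple[int, str]]:
        sub = self.atoms[self.atoms.chain_id == chain]
        ids, names = struc.get_residues(sub)
        return [(int(i), str(n)) for i, n in zip(ids, names)]

    def residue_atoms(self, chain: str, res_id: int) -> struc.AtomArray:
        mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == res_id)
        sub = self.atoms[mask]
        if sub.array_length() == 0:
            raise SiteError(f"no residue {res_id} in chain {chain!r}")
        return sub

    def heavy_coords_excluding(self, chain: str, res_id: int) -> np.ndarray:
        """Heavy-atom coordinates of everything except one residue."""
        arr = self.atoms
        own = (arr.chain_id == chain) & (arr.res_id == res_id)
        heavy = arr.element != "H"
        return arr.coord[heavy & ~own]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigid-body transformed copy (for invariance checks)."""
        arr = self.atoms.copy()
        arr.coord = arr.coord @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(atoms=arr, source=self.source)


def load_structure(path: str | os.PathLike[str]) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations resolve to the highest-occupancy copy; waters and
    other heteroatoms are retained (flagged on the underlying atom array).
    """
    name = os.fspath(path)
    suffix = os.path.splitext(name)[1].lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            cif = pdbxio.CIFFile.read(name)
            arr = pdbxio.get_structure(cif, model=1, altloc="occupancy")
        else:
            pdb = pdbio.PDBFile.read(name)
            arr = pdbio.get_structure(pdb, model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse structure file {name}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"{name}: no atom records")
    return StructureModel(atoms=arr, source=name)


@dataclass(frozen=True)
class DonorSite:
    chain: str
    res_id: int
    res_name: str


def find_native_donors(model: StructureModel) -> list[DonorSite]:
    """All Trp and Tyr residues, tagged with their chain."""
    donors: list[DonorSite] = []
    for chain in model.chains:
        for res_id, res_name in model.residues(chain):
            if res_name in DONOR_RESIDUES:
                donors.append(DonorSite(chain, res_id, res_name))
    return donors


# ---------------------------------------------------------------------------
# Rotamer ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingParams:
    """Settings for the simplified rotamer sampler.

    ``chi_values`` are the dihedral branches (degrees) sampled at every
    rotatable bond.  A conformer is rejected when its fluorophore reference
    point comes within ``clash_cutoff`` Angstrom of any heavy atom outside
    the site's own residue.  With ``weighting="boltzmann"`` survivors are
    down-weighted smoothly by residual proximity instead of uniformly.
    """

    chi_values: tuple[float, ...] = (-60.0, 60.0, 180.0)
    clash_cutoff: float = 2.5
    weighting: str = "uniform"  # "uniform" | "boltzmann"
    boltzmann_radius: float = 4.0
    boltzmann_scale: float = 1.0


# Pseudo-atom topology per label type.  Each stage is
# (bond_length_A, bond_angle_deg, dihedral): dihedral "chi" consumes the
# next sampled chi value, a float is fixed, "axial" extends the previous
# bond (used when the ring centroid sits on the rotation axis).
# The reference point is the final stage.
_LABEL_TOPOLOGY: dict[str, list[tuple[float, float, object]]] = {
    # CB-CG, then indole ring-system centroid
    "TRP": [(1.50, 113.6, "chi"), (2.20, 150.0, "chi")],
    # CB-CG, then phenol ring centroid: on the CB-CG axis, chi2 moves nothing
    "TYR": [(1.51, 113.9, "chi"), (1.39, 180.0, "axial")],
    # CB-CG into the acridone, then the tricyclic centroid further out
    "ACD": [(1.51, 113.6, "chi"), (3.60, 150.0, "chi")],
}


@dataclass(frozen=True)
class LabelEnsemble:
    """Weighted fluorophore reference points for one labeled site."""

    site: tuple[str, int]
    label_type: str
    points: np.ndarray  # (K, 3) Angstrom
    weights: np.ndarray  # (K,) sums to 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.shape[0] != w.size or w.size < 1:
            raise ValueError("points and weights must align, length >= 1")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    def __len__(self) -> int:
        return int(self.weights.size)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float
                ) -> np.ndarray:
    """Natural-extension placement: new atom D bonded to ``c``.

    Satisfies |CD| = bond, angle(B,C,D) = angle_deg and
    dihedral(A,B,C,D) = dihedral_deg.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_frame(res: struc.AtomArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = {}
    for name in ("N", "CA", "C", "CB"):
        sel = res[res.atom_name == name]
        if sel.array_length() > 0:
            coords[name] = sel.coord[0].astype(float)
    for name in ("N", "CA", "C"):
        if name not in coords:
            raise SiteError(f"backbone atom {name} missing at site")
    n, ca, c = coords["N"], coords["CA"], coords["C"]
    if "CB" in coords:
        cb = coords["CB"]
    else:  # idealised CB for Gly or stripped side chains
        cb = _place_atom(c, n, ca, 1.53, 110.5, -122.0)
    return n, ca, cb


def sample_conformers(model: StructureModel, site: tuple[str, int],
                      label_type: str, params: SamplingParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """All candidate reference points and their chi combinations.

    Returns ``(points, chis)`` before any clash filtering; used both by the
    ensemble builder and by brute-force oracles in tests.
    """
    label_type = label_type.upper()
    if label_type not in _LABEL_TOPOLOGY:
        raise ValueError(f"unknown label type {label_type!r}")
    chain, res_id = site
    res = model.residue_atoms(chain, res_id)
    n, ca, cb = _backbone_frame(res)
    topology = _LABEL_TOPOLOGY[label_type]
    n_chi = sum(1 for _, _, d in topology if d == "chi")
    points, chis = [], []
    for combo in itertools.product(params.chi_values, repeat=n_chi):
        frame = [n, ca, cb]  # last three positions define the next placement
        it = iter(combo)
        for bond, angle, dihedral in topology:
            a, b, c = frame[-3], frame[-2], frame[-1]
            if dihedral == "axial":
                direction = c - b
                new = c + bond * direction / np.linalg.norm(direction)
            else:
                chi = next(it) if dihedral == "chi" else float(dihedral)
                new = _place_atom(a, b, c, bond, angle, chi)
            frame.append(new)
        points.append(frame[-1])
        chis.append(combo)
    pts = np.asarray(points)
    # axial stages can make distinct chi combos coincide; deduplicate
    _, keep = np.unique(np.round(pts, 6), axis=0, return_index=True)
    keep = np.sort(keep)
    return pts[keep], np.asarray(chis, dtype=float)[keep]


def build_label_ensemble(
    model: StructureModel,
    site: tuple[str, int],
    label_type: str,
    params: SamplingParams = SamplingParams(),
) -> LabelEnsemble:
    """Clash-filtered rotamer ensemble of fluorophore reference points.

    Conformers whose reference point lies within ``params.clash_cutoff`` of
    any heavy atom outside the site's own residue are rejected; the
    survivors get uniform (or soft Boltzmann) weights.
    """
    chain, res_id = site
    points, _ = sample_conformers(model, site, label_type, params)
    env = model.heavy_coords_excluding(chain, res_id)
    if env.shape[0] > 0:
        dmin = np.min(
            np.linalg.norm(points[:, None, :] - env[None, :, :], axis=2), axis=1
        )
    else:
        dmin = np.full(points.shape[0], np.inf)
    survivors = dmin >= params.clash_cutoff
    if not np.any(survivors):
        raise EmptyEnsembleError(
            f"all {points.shape[0]} conformers clash at {site} "
            f"(cutoff {params.clash_cutoff} A); consider loosening the cutoff"
        )
    pts = points[survivors]
    if params.weighting == "uniform":
        w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    elif params.weighting == "boltzmann":
        d = dmin[survivors]
        penalty = np.clip(params.boltzmann_radius - d, 0.0, None) ** 2
        w = np.exp(-penalty / params.boltzmann_scale)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown weighting {params.weighting!r}")
    return LabelEnsemble(site=(chain, int(res_id)), label_type=label_type.upper(),
                         points=pts, weights=w)


def ensembles_to_pdb(ensembles: list[LabelEnsemble],
                     path: str | os.PathLike[str]) -> None:
    """Write reference points as a multi-model PDB (one model per rotamer).

    Each model holds one pseudo-atom per ensemble so the spread of rotamer
    clouds can be inspected in a molecular viewer.
    """
    n_models = max(len(e) for e in ensembles)
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        for m in range(n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            serial = 1
            for e in ensembles:
                if m >= len(e):
                    continue
                x, y, z = e.points[m]
                chain = (e.site[0] or "A")[0]
                fh.write(
                    f"HETATM{serial:5d}  C   {e.label_type:<3s} {chain}"
                    f"{e.site[1]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{e.weights[m]:6.2f}  0.00           C\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Distances and efficiencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceDistribution:
    """Weighted donor-acceptor distance samples between two ensembles."""

    distances: np.ndarray
    weights: np.ndarray
    donor_site: tuple[str, int]
    acceptor_site: tuple[str, int]

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        w = w / w.sum()
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "weights", w)
        if np.any(d <= 0):
            raise DegenerateDistanceError("zero or negative distance in distribution")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.distances))


def distance_distribution(donor: LabelEnsemble, acceptor: LabelEnsemble
                          ) -> DistanceDistribution:
    """All pairwise distances with product-of-rotamer weights."""
    diff = donor.points[:, None, :] - acceptor.points[None, :, :]
    d = np.linalg.norm(diff, axis=2).ravel()
    w = np.outer(donor.weights, acceptor.weights).ravel()
    return DistanceDistribution(
        distances=d, weights=w,
        donor_site=donor.site, acceptor_site=acceptor.site,
    )


def pair_efficiency(dist: DistanceDistribution, r0: float) -> float:
    """Distribution-averaged single-pair Foerster efficiency."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    e = 1.0 / (1.0 + (dist.distances / r0) ** 6)
    return float(np.dot(dist.weights, e))


def _rate_matrices(donor: LabelEnsemble, acceptors: list[LabelEnsemble],
                   r0: float) -> list[np.ndarray]:
    """Per-acceptor (Kd, Ka) matrices of k = (R0/r)^6."""
    mats = []
    for acc in acceptors:
        diff = donor.points[:, None, :] - acc.points[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        if np.any(d <= 0):
            raise DegenerateDistanceError("coincident donor/acceptor points")
        mats.append((r0 / d) ** 6)
    return mats


def donor_efficiency_multi_acceptor(
    donor: LabelEnsemble,
    acceptors: list[LabelEnsemble],
    r0: float,
    n_samples: int = 100_000,
    seed: int = 0,
    method: str = "auto",
    return_se: bool = False,
) -> float | tuple[float, float]:
    """Efficiency of one donor transferring to several independent acceptors.

    For each joint rotamer state (one conformer per ensemble) the transfer
    probability is ``sum_a k_a / (1 + sum_a k_a)`` with ``k_a = (R0/r_a)^6``;
    the result is the weight-averaged expectation over joint states.  The
    state space is enumerated exhaustively when its size is at most 10^4,
    otherwise estimated by seeded Monte Carlo over ``n_samples`` draws.

    With ``return_se=True`` an ``(estimate, standard_error)`` pair is
    returned (the standard error is 0 on the enumeration path).
    """
    if not acceptors:
        raise ValueError("need at least one acceptor ensemble")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    mats = _rate_matrices(donor, acceptors, r0)
    n_states = len(donor) * int(np.prod([len(a) for a in acceptors]))
    enumerate_states = (method == "enumerate") or (
        method == "auto" and n_states <= _ENUMERATION_LIMIT)
    if enumerate_states:
        total = 0.0
        for combo in itertools.product(*(range(len(a)) for a in acceptors)):
            ksum = np.zeros(len(donor))
            w_combo = 1.0
            for mat, acc, j in zip(mats, acceptors, combo):
                ksum += mat[:, j]
                w_combo *= acc.weights[j]
            total += w_combo * float(
                np.dot(donor.weights, ksum / (1.0 + ksum)))
        return (total, 0.0) if return_se else total
    if n_samples < 100:
        raise PrecisionError(
            f"{n_states} joint states are not enumerable and n_samples="
            f"{n_samples} < 100"
        )
    rng = np.random.default_rng(seed)
    di = rng.choice(len(donor), size=n_samples, p=donor.weights)
    ksum = np.zeros(n_samples)
    for mat, acc in zip(mats, acceptors):
        aj = rng.choice(len(acc), size=n_samples, p=acc.weights)
        ksum += mat[di, aj]
    draws = ksum / (1.0 + ksum)
    est = float(np.mean(draws))
    if return_se:
        se = float(np.std(draws, ddof=1) / np.sqrt(n_samples))
        return est, se
    return est


# ---------------------------------------------------------------------------
# Per-construct prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretPrediction:
    """Aggregate predicted efficiency for one acceptor site."""

    construct_id: str
    mode: str  # "all_donors" | "intrasubunit"
    efficiency: float
    per_donor: "object"  # pandas.DataFrame: chain, res_id, type, r0, efficiency

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency < 1.0:
            raise ValueError(f"efficiency {self.efficiency} outside [0, 1)")


def construct_prediction(
    model: StructureModel,
    acd_site: int,
    mode: str = "all_donors",
    donor_weights: dict[str, float] | None = None,
    params: SamplingParams = SamplingParams(),
    r0_values: dict[str, float] | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    distance_average: str = "efficiency",
    construct_id: str | None = None,
) -> FretPrediction:
    """Predicted FRET efficiency for an acceptor placed at one residue.

    The acceptor ensemble is built at ``acd_site`` in every chain.  Each
    native Trp/Tyr donor (excluding any donor at the labeled position,
    which the acceptor replaces) contributes a multi-acceptor efficiency
    computed with its type-specific R0; ``intrasubunit`` mode restricts a
    donor to the acceptor copy in its own chain.  The aggregate is the
    donor-weight average ``sum_d w_d E_d / sum_d w_d`` (equal type weights
    by default).

    ``distance_average="efficiency"`` averages E over the distance
    distribution (the default); ``"distance"`` evaluates E at each
    acceptor's mean distance instead.
    """
    import pandas as pd

    if mode not in ("all_donors", "intrasubunit"):
        raise ValueError(f"unknown mode {mode!r}")
    if distance_average not in ("efficiency", "distance"):
        raise ValueError(f"unknown distance_average {distance_average!r}")
    r0_values = dict(R0_DEFAULTS, **(r0_values or {}))
    donor_weights = {"TRP": 1.0, "TYR": 1.0, **(donor_weights or {})}

    chains = model.chains
    acceptor_by_chain: dict[str, LabelEnsemble] = {}
    for chain in chains:
        names = dict(model.residues(chain))
        if acd_site not in names:
            raise SiteError(f"acceptor site {acd_site} missing in chain {chain!r}")
        acceptor_by_chain[chain] = build_label_ensemble(
            model, (chain, acd_site), "ACD", params)
    if mode == "all_donors" and len(chains) < 2:
        raise SiteError("all_donors mode expects a multi-chain model")

    donors = [d for d in find_native_donors(model) if d.res_id != acd_site]
    rows = []
    for k, d in enumerate(donors):
        ens = build_label_ensemble(model, (d.chain, d.res_id), d.res_name, params)
        if mode == "intrasubunit":
            accs = [acceptor_by_chain[d.chain]]
        else:
            accs = [acceptor_by_chain[c] for c in chains]
        r0 = r0_values[d.res_name]
        if distance_average == "efficiency":
            e_d = donor_efficiency_multi_acceptor(
                ens, accs, r0, n_samples=n_samples, seed=seed + k)
        else:  # E at mean distances
            ksum = sum((r0 / distance_distribution(ens, a).mean) ** 6
                       for a in accs)
            e_d = ksum / (1.0 + ksum)
        rows.append({
            "donor_chain": d.chain, "donor_res_id": d.res_id,
            "donor_type": d.res_name, "r0": r0, "efficiency": e_d,
            "weight": donor_weights[d.res_name],
        })
    if not rows:
        raise SiteError("no native Trp/Tyr donors found in model")
    table = pd.DataFrame(rows)
    agg = float(np.average(table["efficiency"], weights=table["weight"]))
    return FretPrediction(
        construct_id=construct_id or f"site{acd_site}",
        mode=mode, efficiency=agg, per_donor=table,
    )


# ---------------------------------------------------------------------------
# Measured vs predicted
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginFit:
    """Through-origin regression of measured on predicted values."""

    slope_m: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise StatisticsError("need n >= 3 for a reported correlation")


def correlate_and_fit(measured, predicted) -> OriginFit:
    """Pearson correlation plus least-squares slope through the origin.

    The slope is ``m = sum(x*y) / sum(x^2)`` for y = measured,
    x = predicted.
    """
    y = np.asarray(measured, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if x.size != y.size:
        raise StatisticsError("measured and predicted lengths differ")
    if x.size < 3:
        raise StatisticsError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticsError("zero variance in measured or predicted values")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise StatisticsError("all predicted values are zero")
    slope = float(np.dot(x, y)) / sxx
    r = float(np.corrcoef(x, y)[0, 1])
    return OriginFit(slope_m=slope, pearson_r=r, n=int(x.size))
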