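"""Synthetic ground-truth generators for every pipeline stage.

Each generator is seed-deterministic and returns its ground truth next to
the generated data, so parameter-recovery tests never compare against
anything but the generator's own record.

The spectral generator is built so that, at zero noise, the ratio analysis
is *exact*: the acceptor band is forced to zero below a cutoff wavelength
(default 380 nm), which keeps the donor-window scaling free of acceptor
contamination and makes ``ratio_a - ratio_a0 = m * E`` hold to float
precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .flux import FluxTrace
from .ratio import SpectralFretInput
from .spectra import Spectrum, SpectrumKind
from .structure import StructureModel
from .tcspc import DecayHistogram

__all__ = [
    "make_band",
    "SpectraScenario",
    "FretDataset",
    "make_fret_dataset",
    "ToyStructureScenario",
    "HelixBundle",
    "make_helix_bundle",
    "make_decay",
    "make_flux_trace",
]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def make_band(center: float, width: float, amplitude: float,
              grid: np.ndarray, kind: str = "emission",
              excitation_nm: float | None = 370.0,
              cutoff_below: float | None = None, **meta) -> Spectrum:
    """Gaussian band ``amplitude * exp(-(x-center)^2 / (2 width^2))``.

    ``cutoff_below`` zeroes the band below that abscissa (used to keep
    synthetic acceptor bands out of the donor window exactly).
    """
    x = np.asarray(grid, dtype=float)
    y = amplitude * np.exp(-((x - center) ** 2) / (2.0 * width ** 2))
    if cutoff_below is not None:
        y = np.where(x < cutoff_below, 0.0, y)
    kw = SpectrumKind(kind)
    if kw is not SpectrumKind.EMISSION:
        excitation_nm = None
    return Spectrum(abscissa=x, intensity=y, kind=kw,
                    excitation_nm=excitation_nm, **meta)


@dataclass(frozen=True)
class SpectraScenario:
    """Ground-truth parameters for one synthetic spectral-FRET replicate."""

    true_efficiency: float = 0.3
    ratio_a0_true: float = 0.5
    proportionality_m: float = 0.8
    donor_center: float = 335.0
    donor_width: float = 25.0
    acceptor_center: float = 420.0
    acceptor_width: float = 30.0
    donor_quench: float | None = None  # defaults to true_efficiency
    noise_sd: float = 0.0  # fraction of each spectrum's peak
    seed: int = 0
    grid_start: float = 300.0
    grid_stop: float = 500.0
    grid_step: float = 1.0
    acceptor_cutoff_nm: float = 380.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_efficiency < 1.0:
            raise ValueError("true_efficiency must be in [0, 1)")
        if self.ratio_a0_true <= 0 or self.proportionality_m <= 0:
            raise ValueError("ratio_a0_true and proportionality_m must be > 0")

    @property
    def quench(self) -> float:
        return (self.true_efficiency if self.donor_quench is None
                else self.donor_quench)

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @property
    def expected_ratio_a(self) -> float:
        return (self.ratio_a0_true
                + self.proportionality_m * self.true_efficiency)

    @property
    def expected_relative_fret(self) -> float:
        return self.proportionality_m * self.true_efficiency


@dataclass(frozen=True)
class FretDataset:
    """Generated replicate plus the free-acceptor reference pair."""

    inputs: SpectralFretInput
    free_f280: Spectrum
    free_f370: Spectrum
    scenario: SpectraScenario


def make_fret_dataset(scenario: SpectraScenario,
                      construct_id: str = "synthetic",
                      condition: str = "apo",
                      replicate: int = 0) -> FretDataset:
    """Construct a spectral-FRET replicate with known truth.

    With donor band D and acceptor band A (zeroed below the cutoff):

    * ``f370 = A``
    * ``f280 = (1 - q) D + (ratio_a0 + m E) A`` with donor quench ``q``
      (default ``E``, keeping donor loss and acceptor gain consistent)
    * ``f280_notag = D``
    * free acceptor: ``f280 = ratio_a0 * A``, ``f370 = A``

    Seeded Gaussian noise (sd = ``noise_sd`` x peak, per spectrum) is added
    last.
    """
    sc = scenario
    grid = sc.grid
    donor = make_band(sc.donor_center, sc.donor_width, 1.0, grid,
                      excitation_nm=280.0)
    acceptor = make_band(sc.acceptor_center, sc.acceptor_width, 1.0, grid,
                         excitation_nm=370.0,
                         cutoff_below=sc.acceptor_cutoff_nm)
    a = acceptor.intensity
    d = donor.intensity
    mix = (1.0 - sc.quench) * d + sc.expected_ratio_a * a

    rng = np.random.default_rng(sc.seed)

    def noisy(y: np.ndarray, excitation: float, sid: str) -> Spectrum:
        if sc.noise_sd > 0:
            y = y + rng.normal(0.0, sc.noise_sd * np.max(np.abs(y)), y.size)
        return Spectrum(abscissa=grid, intensity=y,
                        kind=SpectrumKind.EMISSION, excitation_nm=excitation,
                        sample_id=sid, condition=condition)

    inputs = SpectralFretInput(
        f280=noisy(mix, 280.0, f"{construct_id}_F280"),
        f370=noisy(a, 370.0, f"{construct_id}_F370"),
        f280_notag=noisy(d, 280.0, f"{construct_id}_NoTag"),
        construct_id=construct_id, condition=condition, replicate=replicate,
    )
    free_280 = noisy(sc.ratio_a0_true * a, 280.0, "freeAcd_F280")
    free_370 = noisy(a, 370.0, "freeAcd_F370")
    return FretDataset(inputs=inputs, free_f280=free_280, free_f370=free_370,
                       scenario=sc)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureScenario:
    """Ideal helix bundle with labeled sites at recorded positions.

    ``donor_sites`` maps residue number to ``"TRP"``/``"TYR"``;
    ``acceptor_sites`` lists residue numbers left as host residues for
    label attachment.  Chain ``i`` is the template helix rotated by
    ``chain_rotations_z_deg[i]`` about z and translated by
    ``chain_offsets[i]`` (a 180 degree rotation plus an in-plane offset
    yields a C2-symmetric dimer).  ``obstructions`` are extra free carbon
    atoms (own chain ``X``) used to provoke clashes.
    """

    n_res: int = 20
    chain_offsets: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)
    chain_rotations_z_deg: tuple[float, ...] | None = None
    donor_sites: tuple[tuple[int, str], ...] = ()
    acceptor_sites: tuple[int, ...] = ()
    obstructions: tuple[tuple[float, float, float], ...] = ()
    helix_radius: float = 2.3
    rise_per_res: float = 1.5
    twist_deg: float = 100.0
    seed: int = 0


@dataclass(frozen=True)
class HelixBundle:
    """Generated model plus exact per-site backbone coordinates."""

    model: StructureModel
    scenario: ToyStructureScenario
    ca_coords: dict[tuple[str, int], np.ndarray]
    cb_coords: dict[tuple[str, int], np.ndarray]

    def write_pdb(self, path) -> None:
        f = pdbio.PDBFile()
        pdbio.set_structure(f, self.model.atoms)
        f.write(str(path))


_CHAIN_IDS = "ABCDEFGH"


def _ideal_helix(n_res: int, radius: float, rise: float, twist_deg: float
                 ) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/CB coordinates of an ideal helix along +z."""
    idx = np.arange(-1, n_res + 1)  # virtual flanking CAs for terminal frames
    theta = np.deg2rad(twist_deg) * idx
    ca = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                   rise * idx], axis=1)
    out = {"N": [], "CA": [], "C": [], "CB": []}
    from .structure import _place_atom

    for i in range(1, n_res + 1):
        prev_ca, this_ca, next_ca = ca[i - 1], ca[i], ca[i + 1]
        n = this_ca + 1.46 * _unit(prev_ca - this_ca)
        c = this_ca + 1.52 * _unit(next_ca - this_ca)
        cb = _place_atom(c, n, this_ca, 1.53, 110.5, -122.0)
        out["N"].append(n)
        out["CA"].append(this_ca)
        out["C"].append(c)
        out["CB"].append(cb)
    return {k: np.asarray(v) for k, v in out.items()}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_helix_bundle(scenario: ToyStructureScenario) -> HelixBundle:
    """Build an ideal helix bundle as a parseable structural model."""
    sc = scenario
    backbone = _ideal_helix(sc.n_res, sc.helix_radius, sc.rise_per_res,
                            sc.twist_deg)
    donor_names = dict(sc.donor_sites)
    atoms: list[struc.Atom] = []
    ca_coords: dict[tuple[str, int], np.ndarray] = {}
    cb_coords: dict[tuple[str, int], np.ndarray] = {}
    rotations = sc.chain_rotations_z_deg or (0.0,) * len(sc.chain_offsets)
    if len(rotations) != len(sc.chain_offsets):
        raise ValueError("chain_rotations_z_deg must match chain_offsets")
    for ci, (offset, rot_deg) in enumerate(zip(sc.chain_offsets, rotations)):
        chain = _CHAIN_IDS[ci]
        off = np.asarray(offset, dtype=float)
        ang = np.deg2rad(rot_deg)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        for i in range(sc.n_res):
            res_id = i + 1
            res_name = donor_names.get(res_id, "ALA")
            for atom_name, element in (("N", "N"), ("CA", "C"),
                                       ("C", "C"), ("CB", "C")):
                atoms.append(struc.Atom(
                    backbone[atom_name][i] @ rot.T + off,
                    chain_id=chain, res_id=res_id, res_name=res_name,
                    atom_name=atom_name, element=element, hetero=False,
                ))
            ca_coords[(chain, res_id)] = backbone["CA"][i] @ rot.T + off
            cb_coords[(chain, res_id)] = backbone["CB"][i] @ rot.T + off
    for j, pos in enumerate(sc.obstructions):
        atoms.append(struc.Atom(
            np.asarray(pos, dtype=float),
            chain_id="X", res_id=j + 1, res_name="OBS",
            atom_name="C", element="C", hetero=True,
        ))
    arr = struc.array(atoms)
    model = StructureModel(atoms=arr, source="synthetic helix bundle")
    return HelixBundle(model=model, scenario=sc,
                       ca_coords=ca_coords, cb_coords=cb_coords)


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

def make_decay(
    lifetimes,
    amplitudes,
    irf_sigma: float = 0.2,
    n_photons: int = 1_000_000,
    seed: int = 0,
    t_max: float = 100.0,
    dt: float = 0.05,
    irf_center: float = 5.0,
    sampling: str = "photon",
) -> tuple[DecayHistogram, dict]:
    """Photon-count decay histogram with known lifetimes.

    ``amplitudes`` are pre-exponential (intensity-model) amplitudes, the
    same convention the decay fitter reports; component k therefore
    contributes a photon share proportional to ``a_k * tau_k``.

    ``sampling="photon"`` draws individual photon arrival times from the
    exponential mixture, jitters them by a Gaussian IRF of width
    ``irf_sigma`` centered at ``irf_center``, and histograms them (photons
    falling outside the window are dropped).  ``sampling="exact"`` writes
    the noiseless expected counts instead and only supports a delta IRF
    (``irf_sigma = 0``).
    """
    taus = np.asarray(lifetimes, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if taus.size != amps.size or np.any(taus <= 0) or np.any(amps < 0):
        raise ValueError("invalid lifetimes/amplitudes")
    amps = amps / amps.sum()
    # pre-exponential amplitudes: component k contributes a_k * tau_k photons
    photon_share = amps * taus
    photon_share = photon_share / photon_share.sum()
    edges = np.arange(0.0, t_max + dt / 2, dt)
    centers = edges[:-1] + dt / 2

    if sampling == "exact":
        if irf_sigma > 0:
            raise ValueError("exact sampling supports delta IRF only")
        # expected counts: integral of the mixture over each bin
        counts = np.zeros_like(centers)
        for share, tau in zip(photon_share, taus):
            rel0 = np.clip(edges[:-1] - irf_center, 0, None)
            rel1 = np.clip(edges[1:] - irf_center, 0, None)
            counts += n_photons * share * (np.exp(-rel0 / tau)
                                           - np.exp(-rel1 / tau))
        irf_counts = None
    elif sampling == "photon":
        rng = np.random.default_rng(seed)
        comp = rng.choice(taus.size, size=n_photons, p=photon_share)
        arrivals = irf_center + rng.exponential(taus[comp])
        if irf_sigma > 0:
            arrivals = arrivals + rng.normal(0.0, irf_sigma, n_photons)
        counts, _ = np.histogram(arrivals, bins=edges)
        counts = counts.astype(float)
        if irf_sigma > 0:
            irf_shape = np.exp(-((centers - irf_center) ** 2)
                               / (2.0 * irf_sigma ** 2))
            irf_counts = 1e6 * irf_shape / irf_shape.sum()
        else:
            irf_counts = None
    else:
        raise ValueError(f"unknown sampling {sampling!r}")

    truth = {
        "lifetimes": taus, "amplitudes": amps,
        "photon_share": photon_share,
        "mean_lifetime": float(np.dot(amps, taus)),
        "irf_sigma": irf_sigma, "irf_center": irf_center,
        "n_photons": n_photons, "seed": seed,
    }
    return DecayHistogram(time_bins=centers, counts=counts,
                          irf_counts=irf_counts), truth


# ---------------------------------------------------------------------------
# Flux traces
# ---------------------------------------------------------------------------

def make_flux_trace(
    extent: float = 0.6,
    rate: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_val: float = 180.0,
    t_cccp: float = 480.0,
    t_end: float = 600.0,
    dt: float = 5.0,
    gain: float = 1000.0,
    offset: float = 100.0,
) -> tuple[FluxTrace, dict]:
    """Three-phase flux trace: baseline, exponential quench, CCCP floor.

    The underlying normalized signal is 1 during the baseline, relaxes as
    ``1 - extent * (1 - exp(-rate (t - t_val)))`` after valinomycin, and
    drops to 0 at CCCP; the raw trace applies gain/offset and optional
    seeded Gaussian noise (sd in normalized units).
    """
    if not 0.0 <= extent <= 1.0:
        raise ValueError("extent must be in [0, 1]")
    t = np.arange(0.0, t_end + dt / 2, dt)
    norm = np.ones_like(t)
    quench = (t >= t_val) & (t < t_cccp)
    norm[quench] = 1.0 - extent * (1.0 - np.exp(-rate * (t[quench] - t_val)))
    norm[t >= t_cccp] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        norm = norm + rng.normal(0.0, noise_sd, t.size)
    raw = offset + gain * norm
    trace = FluxTrace(time=t, fluorescence=raw,
                      events=(("valinomycin", t_val), ("cccp", t_cccp)))
    truth = {"extent": extent, "rate": rate, "noise_sd": noise_sd,
             "gain": gain, "offset": offset, "t_val": t_val,
             "t_cccp": t_cccp, "seed": seed}
    return trace, truth
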