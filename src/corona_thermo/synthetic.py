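"""Synthetic inputs with the statistical structure each analysis assumes.

Every generator is the exact forward model of its paired analysis operation,
plus (by default) 1 % multiplicative Gaussian noise, so each downstream fit
can be validated by parameter recovery without any external data:

* quenching titrations — linear or modified Stern–Volmer response;
* ITC isotherms — the one-set-of-sites forward model under the reference
  experimental design (208 µL cell, 30 µM protein, 900 µM amphiphile
  syringe, 19 × 2 µL injections, N_agg = 17) with additive baseline noise;
* CD spectra — helicity-weighted mix of an α-helix basis (negative bands at
  208/222 nm, depth −33,000 deg cm² dmol⁻¹ at 208 nm) and a coil basis
  (−4,000 at 208 nm), converted to observed mdeg;
* thermal melts — two-state sigmoids at 222 nm over 25–95 °C;
* toy micelle/protein bead complexes with planted contacts and salt
  bridges, and ideal-helix / extended-chain backbones for the
  secondary-structure operators.

Determinism: the same :class:`GeneratorSpec` yields bit-identical output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import InjectionTable, SpectrumTable, TitrationTable, Trajectory
from . import itc as _itc
from .circular_dichroism import MRE_COIL_208, MRE_HELIX_208

logger = logging.getLogger("corona_thermo")

__all__ = [
    "GeneratorSpec",
    "PAPER_DEFAULTS",
    "PaperDefaults",
    "gen_quenching",
    "gen_itc",
    "default_itc_design",
    "gen_cd_spectrum",
    "gen_melt_curve",
    "gen_toy_complex",
    "gen_ideal_helix",
    "gen_extended_chain",
    "gen_two_strand_sheet",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed and noise level shared by all generators."""

    seed: int = 0
    noise_sd_rel: float = 0.01  # multiplicative Gaussian noise fraction

    def __post_init__(self):
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PaperDefaults:
    """Reference parameter set of the HSA/amphiphilic-dendrimer system.

    Frozen constants from the published characterization of the system:
    Stern–Volmer constant and fluorescence K_D of the quenching assay, ITC
    affinity and enthalpy, micelle aggregation number and CMC, free and
    maximally-bound helicities, and the micelle-induced melting-point shift.
    """

    k_sv: float = 4.9e4          # M^-1
    k_d_fluor: float = 22.9e-6   # M
    k_d_itc: float = 13.4e-6     # M
    delta_h: float = -4.02       # kcal/mol of protein bound
    n_sites: float = 6.0         # proteins per micelle
    n_agg: int = 17
    cmc: float = 4.5e-6          # M (midpoint of the 3.2-5.7 µM range)
    hsa_conc_fluor: float = 2e-6 # M, fixed protein in the quenching assay
    helix_free: float = 59.3     # %
    helix_bound_max: float = 56.1  # % at the highest amphiphile concentration
    t_m_free: float = 65.0       # °C, configurable
    delta_t_m: float = 3.0       # °C reduction at high micelle excess
    temperature_k: float = 298.15


PAPER_DEFAULTS = PaperDefaults()


def _apply_mult_noise(rng, values: np.ndarray, sd_rel: float,
                      positive: bool = False) -> np.ndarray:
    if sd_rel == 0:
        return values.copy()
    out = values * (1.0 + rng.normal(0.0, sd_rel, size=values.shape))
    if positive:
        bad = out <= 0
        tries = 0
        while bad.any() and tries < 100:
            out[bad] = values[bad] * (1.0 + rng.normal(0.0, sd_rel, bad.sum()))
            bad = out <= 0
            tries += 1
        if tries:
            warnings.warn(f"resampled {int(tries)} noise draws to keep "
                          "intensities positive", stacklevel=3)
    return out


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def _msv_quenched_fraction(ad: np.ndarray, k_d: float, hsa: float) -> np.ndarray:
    """Fraction quenched x = (F0−F)/F0 under the single-site model.

    The modified Stern–Volmer relation (F0−F)/F = [AD]_free/K_D with
    [AD]_free = [AD] − x·[HSA] reduces to the 1:1 binding quadratic
    P·x² − (A + P + K)·x + A = 0.
    """
    b = ad + hsa + k_d
    return (b - np.sqrt(b * b - 4.0 * ad * hsa)) / (2.0 * hsa)


def gen_quenching(spec: GeneratorSpec, model: str = "linear_sv",
                  concs=None, k_sv: float | None = None,
                  k_d: float | None = None,
                  hsa_conc: float | None = None,
                  f0: float = 100.0) -> TitrationTable:
    """Synthetic quenching titration under either Stern–Volmer model.

    ``linear_sv``:   F = F0 / (1 + K_SV·[Q]);
    ``modified_sv``: F from the single-site quadratic at fixed [HSA]
    (default 2 µM).  Multiplicative Gaussian noise; the zero-quencher F0
    row is not included (F0 is measured separately).
    """
    if concs is None:
        concs = np.linspace(2e-6, 20e-6, 10)
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0) or np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be positive and increasing")
    if model == "linear_sv":
        k_sv = PAPER_DEFAULTS.k_sv if k_sv is None else k_sv
        f = f0 / (1.0 + k_sv * concs)
        hsa = 0.0
    elif model == "modified_sv":
        k_d = PAPER_DEFAULTS.k_d_fluor if k_d is None else k_d
        hsa = PAPER_DEFAULTS.hsa_conc_fluor if hsa_conc is None else hsa_conc
        x = _msv_quenched_fraction(concs, k_d, hsa)
        f = f0 * (1.0 - x)
    else:
        raise ValueError(f"unknown model {model!r}")
    f = _apply_mult_noise(spec.rng(), f, spec.noise_sd_rel, positive=True)
    return TitrationTable(analyte_label=model, fixed_species_conc=float(hsa),
                          quencher_conc=concs, intensity=f)


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def default_itc_design(n_injections: int = 19, volume_ul: float = 2.0,
                       cell_volume_ul: float = 208.0,
                       cell_conc: float = 30e-6,
                       syringe_conc: float = 900e-6,
                       temperature_k: float = 298.15) -> InjectionTable:
    """The reference titration design: 208 µL cell with 30 µM protein,
    900 µM amphiphile syringe, 19 × 2 µL injections at 25 °C."""
    return InjectionTable(
        cell_volume_ul=cell_volume_ul, temperature_k=temperature_k,
        cell_conc=cell_conc, syringe_conc=syringe_conc,
        volumes_ul=np.full(n_injections, volume_ul),
        heats_ucal=np.zeros(n_injections))


def gen_itc(spec: GeneratorSpec, design: InjectionTable | None = None,
            params: _itc.BindingParams | None = None,
            n_agg: int | None = None, cmc: float | None = None,
            baseline_sd_ucal: float = 0.1) -> InjectionTable:
    """Synthetic integrated-heat table from the one-set-of-sites model.

    Heats are the noiseless forward-model heats scaled by multiplicative
    Gaussian noise, plus an additive baseline term (default 0.1 µcal SD)
    mimicking integration noise.
    """
    if design is None:
        design = default_itc_design()
    if params is None:
        params = _itc.BindingParams(PAPER_DEFAULTS.k_d_itc,
                                    PAPER_DEFAULTS.delta_h,
                                    PAPER_DEFAULTS.n_sites,
                                    design.temperature_k)
    n_agg = PAPER_DEFAULTS.n_agg if n_agg is None else n_agg
    cmc = PAPER_DEFAULTS.cmc if cmc is None else cmc
    clean = _itc.simulate_isotherm(design, params, n_agg, cmc)
    rng = spec.rng()
    heats = clean * (1.0 + rng.normal(0.0, spec.noise_sd_rel, size=clean.shape))
    heats = heats + rng.normal(0.0, baseline_sd_ucal, size=clean.shape)
    return InjectionTable(
        cell_volume_ul=design.cell_volume_ul,
        temperature_k=design.temperature_k,
        cell_conc=design.cell_conc, syringe_conc=design.syringe_conc,
        volumes_ul=design.volumes_ul.copy(), heats_ucal=heats)


# ---------------------------------------------------------------------------
# circular dichroism
# ---------------------------------------------------------------------------

def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _helix_basis(lam: np.ndarray) -> np.ndarray:
    """α-helix MRE basis: two negative bands (208/222 nm), −33,000 at 208."""
    shape = _gauss(lam, 208.0, 6.5) + 0.95 * _gauss(lam, 222.0, 8.5)
    return MRE_HELIX_208 * shape / np.interp(208.0, lam, shape)


def _coil_basis(lam: np.ndarray) -> np.ndarray:
    """Coil/β MRE basis: broad shallow negative feature, −4,000 at 208."""
    shape = _gauss(lam, 204.0, 12.0)
    return MRE_COIL_208 * shape / np.interp(208.0, lam, shape)


def gen_cd_spectrum(spec: GeneratorSpec, helix_pct: float,
                    cp_molar: float = 2e-6, n_res: int = 585,
                    path_cm: float = 0.1,
                    lambda_nm: np.ndarray | None = None) -> SpectrumTable:
    """Synthetic far-UV CD spectrum (observed mdeg vs nm) at a set helicity.

    MRE(λ) is the helicity-weighted sum of the helix and coil bases; both
    are calibrated only at 208 nm, where the helicity formula reads the
    spectrum — band shapes elsewhere are cosmetic.  MRE is converted to
    observed mdeg through obs = MRE · 10·Cp·n·l, then noise is applied.
    """
    if not (0.0 <= helix_pct <= 100.0):
        raise ValueError("helix_pct must lie in [0, 100]")
    if lambda_nm is None:
        lambda_nm = np.arange(200.0, 261.0, 1.0)
    lam = np.asarray(lambda_nm, dtype=float)
    h = helix_pct / 100.0
    mre = h * _helix_basis(lam) + (1.0 - h) * _coil_basis(lam)
    obs = mre * 10.0 * cp_molar * n_res * path_cm
    obs = _apply_mult_noise(spec.rng(), obs, spec.noise_sd_rel)
    return SpectrumTable(lam, obs, x_label="wavelength_nm",
                         y_label="ellipticity_mdeg")


def gen_melt_curve(spec: GeneratorSpec, t_m: float = 65.0, width: float = 3.0,
                   baselines: tuple[float, float] = (-20.0, -4.0),
                   t_range: tuple[float, float] = (25.0, 95.0),
                   step: float = 1.0) -> SpectrumTable:
    """Two-state melt at 222 nm: θ(T) = θ_F + (θ_U−θ_F)/(1+exp((T_M−T)/w))."""
    t = np.arange(t_range[0], t_range[1] + 0.5 * step, step)
    theta_f, theta_u = baselines
    theta = theta_f + (theta_u - theta_f) / (1.0 + np.exp((t_m - t) / width))
    theta = _apply_mult_noise(spec.rng(), theta, spec.noise_sd_rel)
    return SpectrumTable(t, theta, x_label="temperature_C",
                         y_label="ellipticity_mdeg")


# ---------------------------------------------------------------------------
# toy bead complexes
# ---------------------------------------------------------------------------

_PROTEIN_CHAIN_IDS = "ABCDEFGHIJ"


def _unit_vectors(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_toy_complex(spec: GeneratorSpec, n_proteins: int = 6,
                    n_frames: int = 20, planted=None,
                    n_amphiphiles: int = 17, beads_per_protein: int = 50,
                    head_radius: float = 33.0) -> Trajectory:
    """Bead-scale micelle + protein-corona trajectory with planted contacts.

    The micelle (chain ``M``) is ``n_amphiphiles`` 3-bead amphiphiles with
    tail/linker/head beads layered radially (14/24/33 Å by default); head
    beads are cationic.  Proteins (chains ``A``…) are bead chains on a
    36–44 Å shell with a cationic/anionic/neutral residue pattern.

    ``planted`` is a list of (residue_index, occupancy): planted pair j
    places that residue of protein chain j (cyclic) within 4 Å of the head
    bead of micelle amphiphile j+1 in exactly ceil(occupancy·n_frames)
    frames and > 10 Å away otherwise; the planted residue is made anionic.
    """
    planted = list(planted or [])
    for _, occ in planted:
        if not (0.0 <= occ <= 1.0):
            raise ValueError("planted occupancy must lie in [0, 1]")
    if n_proteins < 1 or n_proteins > len(_PROTEIN_CHAIN_IDS):
        raise ValueError("n_proteins out of range")
    rng = spec.rng()

    names, elements, res_names, res_ids, chains, masses = [], [], [], [], [], []
    coords0 = []

    # micelle: radial 3-bead amphiphiles
    layer_r = {"TAL": head_radius - 19.0, "LNK": head_radius - 9.0,
               "HED": head_radius}
    # quasi-uniform head directions keep amphiphiles well separated, so a
    # planted contact can only ever bridge to its own head bead
    i = np.arange(n_amphiphiles) + 0.5
    phi_s = np.arccos(1.0 - 2.0 * i / n_amphiphiles)
    theta_s = np.pi * (1.0 + 5.0 ** 0.5) * i
    dirs = np.column_stack([np.sin(phi_s) * np.cos(theta_s),
                            np.sin(phi_s) * np.sin(theta_s),
                            np.cos(phi_s)])
    head_atom_index: list[int] = []
    for k in range(n_amphiphiles):
        for bead, rr in layer_r.items():
            if bead == "HED":
                head_atom_index.append(len(coords0))
            coords0.append(dirs[k] * rr)
            names.append(bead[0] + "B")
            elements.append("C")
            res_names.append(bead)
            res_ids.append(k + 1)
            chains.append("M")
            masses.append(100.0)

    # proteins: bead chains on a shell, classes cycling every 3 residues
    class_cycle = ["NEU", "ANI", "NEU", "CAT", "NEU", "NEU", "ANI", "NEU"]
    protein_home: dict[tuple[int, int], int] = {}  # (chain idx, resid) -> atom
    centers = _unit_vectors(rng, n_proteins)
    for p in range(n_proteins):
        u = centers[p]
        # local tangent basis for a compact random walk on the shell
        a = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(a) < 1e-6:
            a = np.cross(u, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(u, a)
        ang = rng.normal(0.0, 0.06, size=(beads_per_protein, 2)).cumsum(axis=0)
        for r in range(beads_per_protein):
            # shell floor 4.6 Å above the heads: un-planted beads can touch
            # (contact cutoff 6.5 Å) but never salt-bridge (cutoff 4.0 Å)
            radius = rng.uniform(37.6, 43.4)
            direction = u + ang[r, 0] * a + ang[r, 1] * b
            direction /= np.linalg.norm(direction)
            protein_home[(p, r + 1)] = len(coords0)
            coords0.append(direction * radius)
            names.append("BB")
            elements.append("C")
            res_names.append(class_cycle[r % len(class_cycle)])
            res_ids.append(r + 1)
            chains.append(_PROTEIN_CHAIN_IDS[p])
            masses.append(110.0)

    coords0 = np.asarray(coords0)
    res_names = np.asarray(res_names)

    # wire planted pairs: pair j -> protein chain j (cyclic), head bead j+1
    plant_atoms, plant_heads, plant_frames = [], [], []
    for j, (resid, occ) in enumerate(planted):
        if j >= n_amphiphiles:
            raise ValueError("more planted pairs than amphiphile heads")
        pchain = j % n_proteins
        if (pchain, resid) not in protein_home:
            raise ValueError(f"planted residue {resid} outside protein chain")
        atom = protein_home[(pchain, resid)]
        res_names[atom] = "ANI"
        n_on = int(np.ceil(occ * n_frames))
        frames_on = np.zeros(n_frames, dtype=bool)
        frames_on[:n_on] = True
        plant_atoms.append(atom)
        plant_heads.append(head_atom_index[j + 1] if j + 1 < n_amphiphiles
                           else head_atom_index[0])
        plant_frames.append(frames_on)

    coords = np.repeat(coords0[None, :, :], n_frames, axis=0)
    # small thermal jitter on protein beads (planted beads excluded)
    prot_mask = np.asarray([c != "M" for c in chains])
    prot_mask[plant_atoms] = False
    jitter = rng.normal(0.0, 0.05, size=(n_frames, int(prot_mask.sum()), 3))
    coords[:, prot_mask, :] += jitter

    for atom, head, frames_on in zip(plant_atoms, plant_heads, plant_frames):
        head_pos = coords0[head]
        outward = head_pos / np.linalg.norm(head_pos)
        on_pos = head_pos + 3.0 * outward     # < 4 Å from the head
        off_pos = head_pos + 12.0 * outward   # > 10 Å from the head
        for f in range(n_frames):
            coords[f, atom, :] = on_pos if frames_on[f] else off_pos

    charge = {"CAT": "cationic", "HED": "cationic", "ANI": "anionic"}
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(names),
        elements=np.asarray(elements),
        residue_names=res_names,
        residue_indices=np.asarray(res_ids, dtype=int),
        chain_ids=np.asarray(chains),
        masses=np.asarray(masses, dtype=float),
        charge_class=np.asarray([charge.get(r, "neutral") for r in res_names]),
    )


# ---------------------------------------------------------------------------
# backbone fixtures for secondary-structure tests
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d from three predecessors."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(dih),
                        bond * np.sin(ang) * np.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_from_dihedrals(n_res: int, phi: float, psi: float,
                             omega: float = 180.0) -> np.ndarray:
    """(n_res, 4, 3) backbone N/CA/C/O from ideal internal coordinates."""
    coords = np.zeros((n_res, 4, 3))
    # seed residue along x
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [_BOND["N-CA"], 0.0, 0.0]
    ang = np.radians(_ANGLE["N-CA-C"])
    coords[0, 2] = coords[0, 1] + _BOND["CA-C"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        n_at, ca, c_at = coords[i, 0], coords[i, 1], coords[i, 2]
        if i < n_res - 1:
            n_next = _place(n_at, ca, c_at, _BOND["C-N"],
                            _ANGLE["CA-C-N"], psi)
            ca_next = _place(ca, c_at, n_next, _BOND["N-CA"],
                             _ANGLE["C-N-CA"], omega)
            c_next = _place(c_at, n_next, ca_next, _BOND["CA-C"],
                            _ANGLE["N-CA-C"], phi)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = ca_next
            coords[i + 1, 2] = c_next
            # carbonyl O anti to the next N
            coords[i, 3] = _place(n_next, ca, c_at, _BOND["C-O"],
                                  _ANGLE["CA-C-O"], 180.0)
        else:
            coords[i, 3] = _place(n_at, ca, c_at, _BOND["C-O"],
                                  _ANGLE["CA-C-O"], 135.0)
    return coords


def _backbone_to_trajectory(bb: np.ndarray, chain_id: str = "A",
                            offset: np.ndarray | None = None) -> dict:
    n_res = bb.shape[0]
    if offset is not None:
        bb = bb + offset
    names, res_ids = [], []
    coords = []
    for i in range(n_res):
        for k, nm in enumerate(("N", "CA", "C", "O")):
            coords.append(bb[i, k])
            names.append(nm)
            res_ids.append(i + 1)
    return {
        "coords": np.asarray(coords), "names": names, "res_ids": res_ids,
        "chain": chain_id,
    }


def _assemble(parts: list[dict]) -> Trajectory:
    coords = np.concatenate([p["coords"] for p in parts])[None, :, :]
    names = np.concatenate([np.asarray(p["names"]) for p in parts])
    res_ids = np.concatenate([np.asarray(p["res_ids"], dtype=int)
                              for p in parts])
    chains = np.concatenate([np.full(len(p["names"]), p["chain"])
                             for p in parts])
    elements = np.where(np.char.startswith(names.astype(str), "O"), "O",
                        np.where(np.char.startswith(names.astype(str), "N"),
                                 "N", "C"))
    from .io_formats import ATOMIC_MASSES
    masses = np.asarray([ATOMIC_MASSES[e] for e in elements])
    return Trajectory(
        coords=coords, atom_names=names, elements=elements,
        residue_names=np.full(len(names), "ALA"),
        residue_indices=res_ids, chain_ids=chains, masses=masses,
        charge_class=np.full(len(names), "neutral"))


def gen_ideal_helix(n_res: int) -> Trajectory:
    """Single-frame canonical α-helix backbone (φ = −57°, ψ = −47°)."""
    bb = _backbone_from_dihedrals(n_res, phi=-57.0, psi=-47.0)
    return _assemble([_backbone_to_trajectory(bb)])


def gen_extended_chain(n_res: int) -> Trajectory:
    """Fully extended backbone (φ = ψ = 180°): no helix assignable."""
    bb = _backbone_from_dihedrals(n_res, phi=180.0, psi=180.0)
    return _assemble([_backbone_to_trajectory(bb)])


def gen_two_strand_sheet(n_res: int, spacing: float = 4.8) -> Trajectory:
    """Two parallel β-strand-like chains (bridge-ladder fixture).

    The second strand is displaced along the carbonyl direction (projected
    perpendicular to the strand axis), where the backbone C=O / N–H groups
    face each other and form the inter-strand hydrogen-bond ladder.
    """
    bb = _backbone_from_dihedrals(n_res, phi=-139.0, psi=135.0)
    axis = bb[-1, 1] - bb[0, 1]
    axis /= np.linalg.norm(axis)
    perp = bb[2, 3] - bb[2, 2]          # a representative C->O direction
    perp -= axis * (perp @ axis)
    perp /= np.linalg.norm(perp)
    p1 = _backbone_to_trajectory(bb, chain_id="A")
    p2 = _backbone_to_trajectory(bb, chain_id="B", offset=spacing * perp)
    return _assemble([p1, p2])
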