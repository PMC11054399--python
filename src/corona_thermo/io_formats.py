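"""Domain containers and file formats shared by every analysis stage.

All downstream modules consume only the types defined here:

* :class:`TitrationTable`  — fluorescence quenching titrations,
* :class:`InjectionTable`  — integrated ITC heats with the injection design,
* :class:`SpectrumTable`   — CD spectra and thermal melts,
* :class:`Trajectory`      — multi-frame bead/atom coordinate sets.

External formats are deliberately minimal: RFC-4180 CSV with a unit tag in
the column name (``conc_uM``), multi-model PDB v3.3 for trajectories, and a
JSON run configuration with a versioned schema key.  Readers never silently
drop rows or atoms; every exclusion raises or is logged with a count.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

logger = logging.getLogger("corona_thermo")

__all__ = [
    "FormatError",
    "ConfigError",
    "StructureError",
    "TitrationTable",
    "InjectionTable",
    "SpectrumTable",
    "Trajectory",
    "RunConfig",
    "read_titration_csv",
    "write_titration_csv",
    "read_injection_csv",
    "write_injection_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "load_config",
    "dump_config",
    "ATOMIC_MASSES",
    "CATIONIC_RESIDUES",
    "ANIONIC_RESIDUES",
]


class FormatError(ValueError):
    """A tabular input violates the format contract (names the offending row)."""


class ConfigError(ValueError):
    """A configuration file violates the schema (names the offending key)."""


class StructureError(ValueError):
    """A structure/trajectory file is internally inconsistent."""


# masses in amu; beads in toy systems carry explicit masses instead
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}
DEFAULT_MASS = 12.0

# residue-name → formal charge class (side-chain / head-group at pH 7.4)
CATIONIC_RESIDUES = {"ARG", "LYS", "HIS", "HED", "CAT"}
ANIONIC_RESIDUES = {"ASP", "GLU", "ANI"}


def _charge_class(res_name: str) -> str:
    if res_name in CATIONIC_RESIDUES:
        return "cationic"
    if res_name in ANIONIC_RESIDUES:
        return "anionic"
    return "neutral"


# ---------------------------------------------------------------------------
# tabular domain types
# ---------------------------------------------------------------------------

@dataclass
class TitrationTable:
    """Quencher concentration vs fluorescence intensity.

    Concentrations are molar internally regardless of the unit tag used on
    disk; intensities are in arbitrary fluorescence units.
    """

    analyte_label: str
    fixed_species_conc: float  # M; the species held constant (e.g. HSA)
    quencher_conc: np.ndarray  # M, strictly increasing
    intensity: np.ndarray      # a.u., > 0

    def __post_init__(self) -> None:
        self.quencher_conc = np.asarray(self.quencher_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.quencher_conc.shape != self.intensity.shape:
            raise FormatError("concentration and intensity columns differ in length")
        if len(self.quencher_conc) < 3:
            raise FormatError(
                f"titration needs >= 3 points, got {len(self.quencher_conc)}"
            )
        diffs = np.diff(self.quencher_conc)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise FormatError(
                "quencher concentrations must be strictly increasing; "
                f"row {i + 2} repeats or reverses {self.quencher_conc[i]:g} M"
            )
        if np.any(self.intensity <= 0):
            i = int(np.argmax(self.intensity <= 0))
            raise FormatError(f"non-positive intensity at row {i + 1}")

    def __len__(self) -> int:
        return len(self.quencher_conc)


@dataclass
class InjectionTable:
    """ITC injection design plus integrated per-injection heats."""

    cell_volume_ul: float
    temperature_k: float
    cell_conc: float     # M, species in the cell (protein)
    syringe_conc: float  # M, titrant in the syringe (total AD)
    volumes_ul: np.ndarray
    heats_ucal: np.ndarray

    def __post_init__(self) -> None:
        self.volumes_ul = np.asarray(self.volumes_ul, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.cell_volume_ul <= 0:
            raise FormatError("cell volume must be positive")
        if self.volumes_ul.shape != self.heats_ucal.shape:
            raise FormatError("volume and heat columns differ in length")
        if len(self.volumes_ul) < 2:
            raise FormatError(f"need >= 2 injections, got {len(self.volumes_ul)}")
        if np.any(self.volumes_ul <= 0):
            i = int(np.argmax(self.volumes_ul <= 0))
            raise FormatError(f"non-positive injection volume at row {i + 1}")

    def __len__(self) -> int:
        return len(self.volumes_ul)


@dataclass
class SpectrumTable:
    """Generic x/y table: wavelength (nm) or temperature (°C) vs signal."""

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "ellipticity_mdeg"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise FormatError("x and y columns differ in length")
        d = np.diff(self.x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError("x axis must be strictly monotone")

    def __len__(self) -> int:
        return len(self.x)


# ---------------------------------------------------------------------------
# trajectory domain type
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of coordinates (Å) with per-atom annotations.

    ``charge_class`` holds the formal charge class of the parent group
    (``cationic``/``anionic``/``neutral``), assigned from residue names on
    read and used by the salt-bridge analysis.
    """

    coords: np.ndarray        # (n_frames, n_atoms, 3) Å
    atom_names: np.ndarray    # (n_atoms,) str
    elements: np.ndarray      # (n_atoms,) str
    residue_names: np.ndarray
    residue_indices: np.ndarray  # 1-based, PDB convention
    chain_ids: np.ndarray
    masses: np.ndarray        # amu
    charge_class: np.ndarray  # {cationic, anionic, neutral}

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        n = self.coords.shape[1]
        for name in ("atom_names", "elements", "residue_names", "residue_indices",
                     "chain_ids", "masses", "charge_class"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise StructureError(f"{name} has {len(arr)} entries for {n} atoms")
            setattr(self, name, arr)
        self.masses = self.masses.astype(float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# CSV readers/writers
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def _parse_conc_column(df: pd.DataFrame, stem: str) -> tuple[str, float]:
    """Find a column ``stem`` or ``stem_<unit>`` and return (name, scale-to-M)."""
    for col in df.columns:
        if col == stem:
            return col, 1.0
        if col.startswith(stem + "_"):
            unit = col[len(stem) + 1:]
            if unit not in _UNIT_SCALE:
                raise FormatError(f"unknown unit suffix {unit!r} on column {col!r}")
            return col, _UNIT_SCALE[unit]
    raise FormatError(f"missing required column {stem!r} (unit-tagged allowed)")


def _read_numeric_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise FormatError(f"non-numeric cell in column {col!r} at line {row}")
        df[col] = coerced
    return df


def read_titration_csv(path, analyte_label: str = "",
                       fixed_species_conc: float = 0.0) -> TitrationTable:
    """Read a two-column quenching titration (concentration, intensity).

    The concentration column is named ``conc`` with an optional unit suffix
    (``conc_uM``); rows are sorted by concentration on read.
    """
    df = _read_numeric_csv(path)
    ccol, scale = _parse_conc_column(df, "conc")
    icol = "intensity" if "intensity" in df.columns else None
    if icol is None:
        raise FormatError("missing required column 'intensity'")
    if len(df) < 3:
        raise FormatError(f"titration needs >= 3 rows, got {len(df)}")
    df = df.sort_values(ccol, kind="stable")
    return TitrationTable(
        analyte_label=analyte_label,
        fixed_species_conc=fixed_species_conc,
        quencher_conc=df[ccol].to_numpy() * scale,
        intensity=df[icol].to_numpy(),
    )


def write_titration_csv(table: TitrationTable, path) -> None:
    pd.DataFrame({
        "conc_M": table.quencher_conc,
        "intensity": table.intensity,
    }).to_csv(path, index=False, float_format="%.12g")


def read_injection_csv(path) -> InjectionTable:
    """Read an ITC table: design in ``#``-prefixed header keys, then rows.

    Layout::

        # cell_volume_ul=208
        # temperature_K=298.15
        # cell_conc_M=3e-05
        # syringe_conc_M=0.0009
        volume_ul,heat_ucal
        2,-1.53
        ...
    """
    meta: dict[str, float] = {}
    text = Path(path).read_text()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            try:
                meta[key.strip()] = float(val)
            except ValueError as exc:
                raise FormatError(f"bad header value for {key.strip()!r}") from exc
        else:
            body_lines.append(line)
    df = _read_numeric_csv(io.StringIO("\n".join(body_lines)))
    for key in ("cell_volume_ul", "temperature_K", "cell_conc_M", "syringe_conc_M"):
        if key not in meta:
            raise FormatError(f"missing header key {key!r}")
    for col in ("volume_ul", "heat_ucal"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    return InjectionTable(
        cell_volume_ul=meta["cell_volume_ul"],
        temperature_k=meta["temperature_K"],
        cell_conc=meta["cell_conc_M"],
        syringe_conc=meta["syringe_conc_M"],
        volumes_ul=df["volume_ul"].to_numpy(),
        heats_ucal=df["heat_ucal"].to_numpy(),
    )


def write_injection_csv(table: InjectionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_ul={table.cell_volume_ul:.12g}\n")
        fh.write(f"# temperature_K={table.temperature_k:.12g}\n")
        fh.write(f"# cell_conc_M={table.cell_conc:.12g}\n")
        fh.write(f"# syringe_conc_M={table.syringe_conc:.12g}\n")
        pd.DataFrame({
            "volume_ul": table.volumes_ul,
            "heat_ucal": table.heats_ucal,
        }).to_csv(fh, index=False, float_format="%.12g")


def read_spectrum_csv(path) -> SpectrumTable:
    df = _read_numeric_csv(path)
    if df.shape[1] != 2:
        raise FormatError(f"spectrum CSV needs exactly 2 columns, got {df.shape[1]}")
    xcol, ycol = df.columns
    return SpectrumTable(df[xcol].to_numpy(), df[ycol].to_numpy(),
                         x_label=xcol, y_label=ycol)


def write_spectrum_csv(spec: SpectrumTable, path) -> None:
    pd.DataFrame({spec.x_label: spec.x, spec.y_label: spec.y}).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# multi-model PDB trajectories
# ---------------------------------------------------------------------------

def read_pdb_trajectory(path) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Residue indices are preserved as read (1-based); masses come from an
    element lookup.  Unknown elements get a warning and the default mass
    12.0 amu.  Models with differing atom counts raise a
    :class:`StructureError` naming the first offending model.
    """
    pdb = bpdb.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        _raise_inconsistent_models(path, exc)
        raise
    coords = np.asarray(stack.coord, dtype=float)
    elements = np.asarray([e.upper() for e in stack.element])
    masses = np.empty(len(elements))
    unknown = 0
    for i, el in enumerate(elements):
        if el in ATOMIC_MASSES:
            masses[i] = ATOMIC_MASSES[el]
        else:
            masses[i] = DEFAULT_MASS
            unknown += 1
    if unknown:
        warnings.warn(
            f"{unknown} atoms with unknown element; default mass "
            f"{DEFAULT_MASS} amu assigned", stacklevel=2)
    res_names = np.asarray(stack.res_name)
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(stack.atom_name),
        elements=elements,
        residue_names=res_names,
        residue_indices=np.asarray(stack.res_id, dtype=int),
        chain_ids=np.asarray(stack.chain_id),
        masses=masses,
        charge_class=np.asarray([_charge_class(r) for r in res_names]),
    )


def _raise_inconsistent_models(path, exc: Exception) -> None:
    """Re-scan MODEL blocks to name the model whose atom count differs."""
    counts: list[int] = []
    current = 0
    in_model = False
    for line in Path(path).read_text().splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            in_model, current = True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM  ", "HETATM") and in_model:
            current += 1
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise StructureError(
            f"model {bad} has {counts[bad - 1]} atoms, expected {counts[0]}"
        ) from exc


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a :class:`Trajectory` as a multi-model PDB (coords to 1e-3 Å)."""
    n = traj.n_atoms
    atoms = bst.AtomArray(n)
    atoms.atom_name = traj.atom_names.astype("U6")
    atoms.element = traj.elements.astype("U2")
    atoms.res_name = traj.residue_names.astype("U5")
    atoms.res_id = traj.residue_indices.astype(int)
    atoms.chain_id = traj.chain_ids.astype("U4")
    stack = bst.AtomArrayStack(traj.n_frames, n)
    for cat in atoms.get_annotation_categories():
        stack.set_annotation(cat, atoms.get_annotation(cat))
    stack.coord = traj.coords.astype(np.float32)
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA_VERSION = 1

_CONFIG_FIELDS: dict[str, type] = {
    "schema_version": int,
    "seed": int,
    "contact_cutoff_A": float,
    "saltbridge_cutoff_A": float,
    "persistence_threshold": float,
    "n_agg": int,
    "cmc_M": float,
    "probe_radius_A": float,
    "sasa_points": int,
    "rdf_bin_width_A": float,
    "rayleigh_halfwidth_nm": float,
    "path_length_cm": float,
}


@dataclass
class RunConfig:
    """All cross-module tunables with their documented defaults."""

    schema_version: int = _CONFIG_SCHEMA_VERSION
    seed: int = 0
    contact_cutoff_A: float = 6.5          # protein–micelle contact definition
    saltbridge_cutoff_A: float = 4.0       # charged heavy-atom N–O criterion
    persistence_threshold: float = 0.5     # stable salt-bridge occupancy
    n_agg: int = 17                        # AD monomers per micelle
    cmc_M: float = 4.5e-6                  # critical micellar concentration
    probe_radius_A: float = 1.4            # water probe for SASA
    sasa_points: int = 960                 # sphere points per atom
    rdf_bin_width_A: float = 0.5
    rayleigh_halfwidth_nm: float = 10.0    # scatter mask in EEM peak search
    path_length_cm: float = 0.1            # CD cell path

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a JSON config; unknown keys and type mismatches are hard errors."""
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    cfg = RunConfig()
    for key, value in data.items():
        if key not in _CONFIG_FIELDS:
            raise ConfigError(f"unknown config key {key!r}")
        want = _CONFIG_FIELDS[key]
        if want is float and isinstance(value, (int, float)) and not isinstance(value, bool):
            value = float(value)
        elif want is int and isinstance(value, int) and not isinstance(value, bool):
            value = int(value)
        else:
            raise ConfigError(
                f"config key {key!r} expects {want.__name__}, got "
                f"{type(value).__name__} ({value!r})")
        setattr(cfg, key, value)
    if cfg.schema_version != _CONFIG_SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {cfg.schema_version}")
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
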