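"""File I/O: spin-system YAML configs, peak-amplitude CSV tables, and
multi-MODEL PDB conformer ensembles.

The PDB reader/writer covers exactly the subset the package produces and
consumes (ATOM/HETATM records framed by MODEL/ENDMDL) and is written here
so that malformed records are reported with their line number and
inter-model atom-count mismatches name the offending model -- positioned,
fatal errors are part of the contract.  Occupancy and B-factor columns are
passed through untouched.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import yaml

from .ensemble import ConformerEnsemble
from .noesy import PeakAmplitudes
from .spin import SpinSystem, build_spin_system, system_to_config

__all__ = [
    "read_spin_config",
    "write_spin_config",
    "read_peak_table",
    "write_peak_table",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "config_hash",
    "provenance_header",
]

PEAK_COLUMNS = ["source", "destination", "amplitude", "experiment", "mixing", "loops"]


class ParseError(ValueError):
    """Positioned parse failure."""


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def provenance_header(seed=None, config: dict | None = None) -> list[str]:
    from . import __version__

    lines = [f"# lprosy {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


# -- spin-system configs ---------------------------------------------------

def read_spin_config(path) -> SpinSystem:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return build_spin_system(config)


def write_spin_config(system: SpinSystem, path) -> None:
    with open(path, "w") as fh:
        # pool order is semantic (it fixes the magnetization-vector layout)
        yaml.safe_dump(system_to_config(system), fh, sort_keys=False)


# -- peak tables -----------------------------------------------------------

def write_peak_table(peaks: PeakAmplitudes, path, seed=None, config: dict | None = None) -> None:
    """CSV with columns source,destination,amplitude,experiment,mixing,loops."""
    sched = peaks.schedule
    rows = []
    for src, amp in peaks.diagonal.items():
        rows.append((src, src, amp))
    for (src, dst), amp in peaks.cross.items():
        rows.append((src, dst, amp))
    df = pd.DataFrame(rows, columns=["source", "destination", "amplitude"])
    df["experiment"] = sched.experiment if sched else ""
    if sched is not None:
        df["mixing"] = (
            sched.mixing_time if sched.experiment == "conventional" else sched.per_loop_mixing
        )
        df["loops"] = 1 if sched.experiment == "conventional" else sched.loop_count
    else:
        df["mixing"] = np.nan
        df["loops"] = 1
    with open(path, "w") as fh:
        for line in provenance_header(seed=seed, config=config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_csv_table(path, required_columns) -> pd.DataFrame:
    """Generic comma-separated table with a mandatory header row."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# -- multi-MODEL PDB -------------------------------------------------------

def write_ensemble_pdb(ensemble: ConformerEnsemble, path) -> None:
    occ = ensemble.occupancies
    bfac = ensemble.bfactors
    with open(path, "w") as fh:
        for m in range(ensemble.n_frames):
            fh.write(f"MODEL     {m + 1:>4d}\n")
            for i in range(ensemble.n_atoms):
                x, y, z = ensemble.coords[m, i]
                name = ensemble.atom_names[i]
                # columns per the fixed-width PDB convention
                pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
                fh.write(
                    "ATOM  {serial:>5d} {name:<4s} {res:<3s} A{resid:>4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n".format(
                        serial=i + 1,
                        name=pad_name,
                        res=str(ensemble.resnames[i])[:3],
                        resid=int(ensemble.resids[i]),
                        x=x,
                        y=y,
                        z=z,
                        occ=float(occ[i]) if occ is not None else 1.0,
                        b=float(bfac[i]) if bfac is not None else 0.0,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_ensemble_pdb(path) -> ConformerEnsemble:
    """Parse a multi-MODEL PDB into a :class:`ConformerEnsemble`.

    Atom metadata is taken from the first model; every model must contain
    the same number of atoms or a :class:`ParseError` naming the model is
    raised.  Malformed coordinate records fail with their line number.
    """
    models: list[list[tuple]] = []
    current: list[tuple] | None = None
    model_no = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                model_no += 1
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError(f"{path}:{lineno}: ENDMDL without MODEL")
                models.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    # single-model files without MODEL framing
                    model_no = 1
                    current = []
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ = float(line[54:60]) if line[54:60].strip() else 1.0
                    b = float(line[60:66]) if line[60:66].strip() else 0.0
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate record: {exc}"
                    ) from None
                current.append((name, resname, resid, x, y, z, occ, b))
    if current is not None:
        models.append(current)
    if not models:
        raise ParseError(f"{path}: no coordinate models found")
    n_atoms = len(models[0])
    for m, atoms in enumerate(models, start=1):
        if len(atoms) != n_atoms:
            raise ParseError(
                f"{path}: model {m} has {len(atoms)} atoms, expected {n_atoms}"
            )
    first = models[0]
    coords = np.array(
        [[(a[3], a[4], a[5]) for a in atoms] for atoms in models], dtype=float
    )
    return ConformerEnsemble(
        coords=coords,
        atom_names=[a[0] for a in first],
        resids=np.array([a[2] for a in first]),
        resnames=[a[1] for a in first],
        occupancies=np.array([a[6] for a in first]),
        bfactors=np.array([a[7] for a in first]),
    )
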