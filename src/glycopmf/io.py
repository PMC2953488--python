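"""File I/O: trajectories (multi-frame PDB / XYZ), window TSVs, PMF tables.

All tabular artifacts are TSV with ``#``-prefixed header lines; landmark and
configuration data are JSON.  Units are fixed: Å and kcal/mol, stated in
headers.  Frame indexing is 0-based everywhere.

PDB files are read and written through biotite (coordinates, atom names and
elements only; occupancy/B-factor are ignored).  The XYZ reader/writer is a
small label-preserving implementation: the first column is the frame's free
atom label, which standard XYZ tooling would normalize to an element symbol.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .frames import Frame, RCSpec
from .pmf import Landmarks, PMFProfile, UmbrellaWindow

__all__ = [
    "read_xyz", "write_xyz", "read_pdb", "write_pdb",
    "read_window_tsv", "write_window_tsv", "read_manifest", "write_manifest",
    "read_pmf_tsv", "write_pmf_tsv",
    "read_landmarks_json", "write_landmarks_json",
    "read_rcspecs_json", "write_rcspecs_json",
    "write_series_tsv", "read_series_tsv",
]


# --------------------------------------------------------------------------
# trajectories

def read_xyz(path: str | Path) -> list[Frame]:
    """Read a multi-frame XYZ trajectory with free-string labels."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise InputError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        time = None
        for tok in comment.split():
            if tok.startswith("time="):
                time = float(tok[5:])
        labels, coords = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            if len(parts) < 4:
                raise InputError(f"{path}: malformed atom line {row!r}")
            labels.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elements = tuple(lab[0] if lab else "X" for lab in labels)
        frames.append(Frame(labels=tuple(labels), elements=elements,
                            coords=np.array(coords), time=time))
        i += 2 + n
    if not frames:
        raise InputError(f"{path}: no frames found")
    return frames


def write_xyz(path: str | Path, frames: Sequence[Frame], header: Iterable[str] = ()) -> None:
    """Write frames as multi-frame XYZ; provenance goes into comment lines."""
    prov = " ".join(header)
    out = []
    for idx, fr in enumerate(frames):
        out.append(str(len(fr)))
        comment = f"frame={idx}"
        if fr.time is not None:
            comment += f" time={fr.time:.6g}"
        if prov:
            comment += f" {prov}"
        out.append(comment)
        for lab, xyz in zip(fr.labels, fr.coords):
            out.append(f"{lab} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_pdb(path: str | Path) -> list[Frame]:
    """Read a (multi-model) PDB file into frames; labels are atom names."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if stack.stack_depth() == 0:
        raise InputError(f"{path}: no models found")
    labels = tuple(str(n) for n in stack.atom_name)
    elements = tuple(str(e) for e in stack.element)
    return [
        Frame(labels=labels, elements=elements, coords=np.asarray(stack.coord[m]))
        for m in range(stack.stack_depth())
    ]


def write_pdb(path: str | Path, frames: Sequence[Frame]) -> None:
    """Write frames as a multi-model PDB (labels must fit PDB atom names)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(frames[0])
    arrays = []
    for fr in frames:
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.coords, dtype=np.float32)
        arr.atom_name = np.array(fr.labels)
        arr.element = np.array([e.upper() for e in fr.elements])
        arr.res_id = np.ones(n, dtype=int)
        arr.res_name = np.array(["LIG"] * n)
        arr.chain_id = np.array(["A"] * n)
        arr.hetero = np.array([True] * n)
        arrays.append(arr)
    stack = struc.stack(arrays)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# --------------------------------------------------------------------------
# umbrella windows

def write_window_tsv(path: str | Path, window: UmbrellaWindow, header: Iterable[str] = ()) -> None:
    """Per-window sample file: '# center=<Å> k=<kcal/mol/Å²>' then one sample/line."""
    lines = [f"# center={window.center:.10g} k={window.k:.10g}"]
    lines += [f"# {h}" for h in header]
    lines += [f"{s:.10f}" for s in window.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_tsv(path: str | Path) -> UmbrellaWindow:
    center = k = None
    samples = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("center="):
                    center = float(tok[7:])
                elif tok.startswith("k="):
                    k = float(tok[2:])
            continue
        samples.append(float(line.split()[0]))
    if center is None or k is None:
        raise InputError(f"{path}: missing '# center=... k=...' header")
    if not samples:
        raise InputError(f"{path}: no samples")
    return UmbrellaWindow(center=center, k=k, samples=np.array(samples),
                          label=Path(path).stem)


def write_manifest(path: str | Path, window_files: Sequence[str | Path], meta: dict | None = None) -> None:
    doc = {"windows": [str(p) for p in window_files]}
    if meta:
        doc["meta"] = meta
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Load all windows listed in a JSON manifest (paths relative to it)."""
    p = Path(path)
    try:
        doc = json.loads(p.read_text())
        files = doc["windows"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise InputError(f"{path}: not a valid window manifest") from exc
    windows = []
    for f in files:
        fp = Path(f)
        if not fp.is_absolute():
            fp = p.parent / fp
        if not fp.exists():
            raise InputError(f"manifest entry not found: {fp}")
        windows.append(read_window_tsv(fp))
    return windows


# --------------------------------------------------------------------------
# profiles / landmarks / series

def write_pmf_tsv(path: str | Path, profile: PMFProfile, header: Iterable[str] = ()) -> None:
    lines = [f"# {h}" for h in header]
    lines.append(f"# temperature_K={profile.temperature:.10g}")
    lines.append("# columns: bin_center_A\tG_kcal_per_mol\tcount")
    for x, g, c in zip(profile.bin_centers, profile.G, profile.counts):
        gtxt = f"{g:.10f}" if np.isfinite(g) else "nan"
        lines.append(f"{x:.10f}\t{gtxt}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf_tsv(path: str | Path) -> PMFProfile:
    temperature = 300.0
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("temperature_K="):
                    temperature = float(tok.split("=", 1)[1])
            continue
        parts = line.split("\t")
        rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
    if not rows:
        raise InputError(f"{path}: empty PMF table")
    arr = np.array(rows)
    return PMFProfile(bin_centers=arr[:, 0], G=arr[:, 1], counts=arr[:, 2],
                      temperature=temperature)


def write_landmarks_json(path: str | Path, lm: Landmarks, meta: dict | None = None) -> None:
    doc = lm.to_dict()
    if meta:
        doc["meta"] = meta
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_landmarks_json(path: str | Path) -> Landmarks:
    doc = json.loads(Path(path).read_text())
    return Landmarks(
        reactant_min=doc["reactant_min"], ts_pos=doc["ts_pos"],
        product_min=doc["product_min"], barrier=doc["barrier"],
        delta_g=doc["delta_g"],
    )


def read_rcspecs_json(path: str | Path) -> list[RCSpec]:
    """RC definitions: JSON list of {"name", "terms": [{"a","b","w"}, ...]}."""
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, dict):
        doc = [doc]
    return [RCSpec.from_dict(d) for d in doc]


def write_rcspecs_json(path: str | Path, specs: Sequence[RCSpec]) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in specs], indent=2) + "\n")


def write_series_tsv(path: str | Path, df: pd.DataFrame, header: Iterable[str] = ()) -> None:
    """Per-frame monitor series as TSV with '#' header lines."""
    with open(path, "w") as fh:
        for h in header:
            fh.write(f"# {h}\n")
        fh.write("# columns: " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.8f")


def read_series_tsv(path: str | Path) -> pd.DataFrame:
    cols = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# columns:"):
            cols = line.split(":", 1)[1].split()
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if cols and len(cols) == df.shape[1]:
        df.columns = cols
    return df
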