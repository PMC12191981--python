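"""Path serialization: TSV with a commented metadata header.

One column per path; the header carries dt, Nt, eps, the potential spec
and the seed.  Positions are written with 17 significant digits, which
round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path as FsPath
from typing import Sequence

import numpy as np

from .dynamics import Path, ProcessSpec, TimeGrid
from .potentials import potential_from_spec

__all__ = ["write_paths", "read_paths"]


def write_paths(file, paths: Sequence[Path]) -> None:
    """Write an ensemble of paths (shared grid) to a TSV file."""
    if len(paths) == 0:
        raise ValueError("refusing to write an empty path ensemble")
    grid = paths[0].grid
    proc = paths[0].process
    for p in paths:
        if p.grid != grid:
            raise ValueError("paths live on different time grids")
    header = {
        "dt": grid.dt,
        "n_steps": grid.n_steps,
        "eps": proc.temperature if proc is not None else None,
        "potential": proc.potential.spec() if proc is not None else None,
        "seed": paths[0].provenance.get("seed"),
        "generator": paths[0].provenance.get("generator"),
    }
    mat = np.stack([p.positions for p in paths], axis=1)
    file = FsPath(file)
    with file.open("w") as fh:
        fh.write(f"# pathmeasure paths {json.dumps(header)}\n")
        fh.write("\t".join(f"path_{k}" for k in range(mat.shape[1])) + "\n")
        np.savetxt(fh, mat, fmt="%.17g", delimiter="\t")


def read_paths(file, expected_process: ProcessSpec | None = None) -> list[Path]:
    """Read a TSV path ensemble; optionally enforce metadata consistency.

    Raises if ``expected_process`` disagrees with the stored eps or
    potential spec — running a functional with the wrong temperature
    silently rescales every action, so this fails loudly instead.
    """
    file = FsPath(file)
    with file.open() as fh:
        first = fh.readline()
        if not first.startswith("# pathmeasure paths "):
            raise ValueError(f"{file} is not a pathmeasure path file")
        header = json.loads(first[len("# pathmeasure paths "):])
        mat = np.loadtxt(fh, delimiter="\t", skiprows=1, ndmin=2)
    grid = TimeGrid(dt=header["dt"], n_steps=header["n_steps"])
    if mat.shape[0] != grid.n_steps + 1:
        raise ValueError(
            f"{file}: expected {grid.n_steps + 1} rows, found {mat.shape[0]}"
        )
    process = None
    if header.get("potential") is not None and header.get("eps") is not None:
        process = ProcessSpec(potential_from_spec(header["potential"]), header["eps"])
    if expected_process is not None:
        if process is None:
            raise ValueError(f"{file} carries no process metadata to check against")
        if expected_process.temperature != process.temperature:
            raise ValueError(
                f"temperature mismatch: file has eps={process.temperature}, "
                f"requested eps={expected_process.temperature}"
            )
        if expected_process.potential.spec() != process.potential.spec():
            raise ValueError(
                f"potential mismatch: file has {process.potential.spec()}, "
                f"requested {expected_process.potential.spec()}"
            )
    provenance = {"generator": header.get("generator"), "seed": header.get("seed")}
    return [
        Path(mat[:, k], grid, process=process, provenance={**provenance, "index": k})
        for k in range(mat.shape[1])
    ]
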