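"""File formats: extended XYZ trajectories, TSV time series, HDF5 checkpoints.

Extended XYZ: one frame per snapshot; the comment line carries ``step``,
energy components and (for periodic systems) the box edge as ``key=value``
pairs.  The reader tolerates a missing box for single-chain runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .models import Conformation


@dataclass
class Frame:
    conf: Conformation
    meta: dict = field(default_factory=dict)


def write_xyz(path, frames, mode: str = "w") -> None:
    """Write conformations as an extended-XYZ trajectory.

    ``frames`` is an iterable of :class:`Frame` or bare Conformations.
    """
    with open(path, mode) as fh:
        for fr in frames:
            conf = fr.conf if isinstance(fr, Frame) else fr
            meta = dict(fr.meta) if isinstance(fr, Frame) else {}
            meta.setdefault("n_per_chain", conf.n_per_chain)
            meta.setdefault("n_chains", conf.n_chains)
            if conf.box is not None:
                meta.setdefault("box", conf.box)
            comment = " ".join(
                f"{k}={float(v)!r}" if isinstance(v, float)
                else f"{k}={v}" for k, v in meta.items())
            fh.write(f"{conf.n_beads}\n{comment}\n")
            for c in range(conf.n_chains):
                for x, y, z in conf.chain(c):
                    fh.write(f"C{c} {float(x)!r} {float(y)!r} "
                             f"{float(z)!r}\n")


def _parse_meta(comment: str) -> dict:
    meta = {}
    for tok in comment.split():
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        try:
            meta[k] = int(v)
        except ValueError:
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v
    return meta


def read_xyz(path) -> list[Frame]:
    frames = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            meta = _parse_meta(fh.readline())
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
            npc = int(meta.get("n_per_chain", n))
            nch = int(meta.get("n_chains", n // npc))
            box = meta.get("box")
            frames.append(Frame(Conformation(pos, npc, nch, box), meta))
    return frames


def write_series_tsv(path, series: np.ndarray, columns) -> None:
    """Per-sweep observable table with a documented header."""
    df = pd.DataFrame(series, columns=list(columns))
    with open(path, "w") as fh:
        fh.write("# per-sweep observables; columns:\t" +
                 "\t".join(columns) + "\n")
        df.to_csv(fh, sep="\t", index_label="sweep")


def read_series_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="sweep")


def write_matrix_tsv(path, matrix: np.ndarray, xedges=None, yedges=None) -> None:
    """2D histogram matrix as TSV (row/column edges in comment lines)."""
    with open(path, "w") as fh:
        if xedges is not None:
            fh.write("# xedges\t" + "\t".join(repr(float(x))
                                              for x in xedges) + "\n")
        if yedges is not None:
            fh.write("# yedges\t" + "\t".join(repr(float(y))
                                              for y in yedges) + "\n")
        np.savetxt(fh, matrix, delimiter="\t")


def save_checkpoint(path, conf: Conformation, *, weights=None,
                    sweep: int = 0, seed: int = 0, extra: dict | None = None) -> None:
    """Single-file HDF5 checkpoint: conformation, weights, counters."""
    with h5py.File(path, "w") as h5:
        h5["positions"] = conf.positions
        h5.attrs["n_per_chain"] = conf.n_per_chain
        h5.attrs["n_chains"] = conf.n_chains
        h5.attrs["box"] = -1.0 if conf.box is None else conf.box
        h5.attrs["sweep"] = sweep
        h5.attrs["seed"] = seed
        if weights is not None:
            h5["weight_edges"] = weights.edges
            h5["weight_lnw"] = weights.lnw
        for k, v in (extra or {}).items():
            h5.attrs[k] = v


def load_checkpoint(path):
    from .sampling import WeightTable
    with h5py.File(path, "r") as h5:
        box = float(h5.attrs["box"])
        conf = Conformation(h5["positions"][...],
                            int(h5.attrs["n_per_chain"]),
                            int(h5.attrs["n_chains"]),
                            None if box < 0 else box)
        weights = None
        if "weight_lnw" in h5:
            weights = WeightTable(h5["weight_edges"][...],
                                  h5["weight_lnw"][...])
        meta = {k: h5.attrs[k] for k in h5.attrs}
    return conf, weights, meta
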