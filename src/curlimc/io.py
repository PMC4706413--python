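"""File formats: FASTA sequences (biopython), PDB snapshots (biotite),
tab-separated trajectory tables and weight tables, YAML configs."""
from __future__ import annotations

import gzip as gzip_mod
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chain import PeptideSequence, SystemState
from .ensemble import EnergyGrid, TabulatedWeight

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL"}


# -- FASTA ------------------------------------------------------------------

def read_fasta(path):
    """Sequences from a FASTA file as PeptideSequence objects."""
    return [PeptideSequence(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs, path):
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# -- trajectory tables ------------------------------------------------------

def write_trajectory(record_or_table, path, gzip=False):
    """Trajectory as tab-separated text with header (optionally gzipped).

    The on-disk header names the energy column ``E_total``; in memory the
    tables use ``E``.
    """
    table = getattr(record_or_table, "table", record_or_table)
    path = str(path)
    if gzip and not path.endswith(".gz"):
        path += ".gz"
    table.rename(columns={"E": "E_total"}).to_csv(
        path, sep="\t", index=False, compression="gzip" if gzip else None)
    return path


def read_trajectory(path) -> pd.DataFrame:
    tab = pd.read_csv(str(path), sep="\t",
                      compression="gzip" if str(path).endswith(".gz")
                      else None)
    return tab.rename(columns={"E_total": "E"})


# -- weight tables ----------------------------------------------------------

def write_weight_table(weight: TabulatedWeight, path):
    """Two-column text (bin center, ln w) with a provenance header."""
    g = weight.grid
    with open(path, "w") as fh:
        fh.write(f"# kind: {weight.kind}\n")
        fh.write(f"# iteration: {weight.iteration}\n")
        fh.write(f"# grid: e_min={float(g.e_min)!r} "
                 f"e_max={float(g.e_max)!r} n_bins={g.n_bins}\n")
        fh.write("# columns: bin_center ln_w\n")
        for c, w in zip(g.centers, weight.ln_w):
            fh.write(f"{float(c)!r}\t{float(w)!r}\n")


def read_weight_table(path) -> TabulatedWeight:
    kind, iteration = "multicanonical", 0
    meta = {}
    centers, ln_w = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("kind:"):
                kind = body.split(":", 1)[1].strip()
            elif body.startswith("iteration:"):
                iteration = int(body.split(":", 1)[1])
            elif body.startswith("grid:"):
                for tok in body.split(":", 1)[1].split():
                    k, v = tok.split("=")
                    meta[k] = float(v) if k != "n_bins" else int(v)
        elif line.strip():
            c, w = line.split("\t")
            centers.append(float(c))
            ln_w.append(float(w))
    grid = EnergyGrid(meta["e_min"], meta["e_max"], meta["n_bins"])
    return TabulatedWeight(grid, np.array(ln_w), kind=kind,
                           iteration=iteration)


# -- PDB snapshots ----------------------------------------------------------

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H", "CB": "C",
            "SC": "C"}
_CHAIN_IDS = "ABCDEFGH"


def _atom_array(state: SystemState) -> struc.AtomArray:
    n_total = sum(t.n_atoms for t in state.topologies)
    arr = struc.AtomArray(n_total)
    k = 0
    for c, topo in enumerate(state.topologies):
        seq = topo.seq.residues
        for name, ri, xyz in zip(topo.atom_names, topo.atom_resid,
                                 state.coords[c]):
            arr.coord[k] = xyz
            arr.chain_id[k] = _CHAIN_IDS[c]
            arr.res_id[k] = int(ri) + 1
            arr.res_name[k] = THREE_LETTER[seq[ri]]
            arr.atom_name[k] = name
            arr.element[k] = _ELEMENT[name]
            arr.hetero[k] = False
            k += 1
    return arr


def write_pdb(states, path):
    """Write one state (single model) or a list of states (one model per
    frame, identical topology) to PDB. Chain IDs are A/B/...; backbone
    atoms N/CA/C/O are always present."""
    pdb = PDBFile()
    if isinstance(states, SystemState):
        pdb.set_structure(_atom_array(states))
    else:
        arrays = [_atom_array(s) for s in states]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    pdb.write(str(path))


# -- configs ----------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
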