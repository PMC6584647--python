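"""Coordinate file I/O (PDB / mmCIF via gemmi).

The reduced six-atom representation maps onto standard records: N, CA, C,
O, CB are ATOM records; the SC side-chain-centroid pseudo-atom is written
as a HETATM named ``SC`` within the same residue, which keeps the files
parseable by standard tools.  Ensembles become multi-MODEL files.
"""

from __future__ import annotations

import gemmi
import numpy as np

from ._kernels import ATOM_ORDER, N_SLOTS
from .model import Ensemble, InputError, Structure, aa1to3, aa3to1

__all__ = ["write_structure", "read_structure", "write_ensemble",
           "read_ensemble", "read_backbone_coords"]


def _to_gemmi(structures: list[Structure], name: str = "emnmr") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for m, confs in enumerate(structures if isinstance(structures[0], list)
                              else [structures], start=1):
        model = gemmi.Model(m)
        for s in confs:
            chain = gemmi.Chain(s.chain_id)
            for ri, aa in s.residues:
                res = gemmi.Residue()
                res.name = aa1to3(aa)
                res.seqid = gemmi.SeqId(ri, " ")
                for k, aname in enumerate(ATOM_ORDER):
                    at = gemmi.Atom()
                    at.name = aname
                    at.element = gemmi.Element("N" if aname == "N" else
                                               "O" if aname == "O" else "C")
                    x, y, z = s.coords[(ri - 1) * N_SLOTS + k]
                    at.pos = gemmi.Position(x, y, z)
                    res.add_atom(at)
                res.het_flag = "A"
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure | list[Structure], path) -> None:
    """Write one Structure (or a list of chains, e.g. an assembly)."""
    chains = [structure] if isinstance(structure, Structure) else list(structure)
    _write(_to_gemmi(chains), path)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Each conformer becomes one MODEL."""
    st = _to_gemmi([[c] for c in ensemble.conformers])
    _write(st, path)


def _write(st: gemmi.Structure, path) -> None:
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        doc = st.make_mmcif_document()
        doc.write_file(path)
    else:
        st.write_pdb(path)


def _from_gemmi_model(model: gemmi.Model) -> list[Structure]:
    out = []
    for chain in model:
        seq = []
        coords = []
        for res in chain:
            seq.append(aa3to1(res.name))
            by_name = {a.name: a.pos for a in res}
            missing = [n for n in ATOM_ORDER if n not in by_name]
            if missing:
                raise InputError(
                    f"residue {res.seqid.num} lacks atoms {missing}; not a "
                    "reduced-representation file")
            for n in ATOM_ORDER:
                p = by_name[n]
                coords.append((p.x, p.y, p.z))
        out.append(Structure("".join(seq), np.array(coords), chain.name))
    return out


def _read(path) -> gemmi.Structure:
    try:
        return gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read structure {path}: {exc}") from exc


def read_structure(path) -> Structure | list[Structure]:
    """Read a reduced-representation file; returns a list for multi-chain."""
    st = _read(path)
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    chains = _from_gemmi_model(st[0])
    return chains[0] if len(chains) == 1 else chains


def read_ensemble(path) -> Ensemble:
    """Multi-MODEL file -> Ensemble (energies unknown, set to 0)."""
    st = _read(path)
    confs = []
    for model in st:
        chains = _from_gemmi_model(model)
        if len(chains) != 1:
            raise InputError("ensemble files must be single-chain")
        confs.append(chains[0])
    if not confs:
        raise InputError(f"{path}: no models")
    return Ensemble(confs, np.zeros(len(confs)))


def read_backbone_coords(path, atom_names=("CA",), chain: str | None = None
                         ) -> list[np.ndarray]:
    """Per-model arrays of the named backbone atoms from an arbitrary
    (full-atom, deposited) PDB/mmCIF file.  Used by the deposited-model
    comparison tooling; makes no reduced-representation assumption."""
    st = _read(path)
    wanted = set(atom_names)
    out = []
    for model in st:
        pts = []
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                for a in res:
                    if a.name in wanted:
                        pts.append((a.pos.x, a.pos.y, a.pos.z))
        out.append(np.array(pts))
    return out
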