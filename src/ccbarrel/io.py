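"""Structure and sidecar I/O for assembly models.

PDB/mmCIF reading and writing go through gemmi.  Models are Calpha-only on
output (ATOM records, chain IDs A-F..., 1-based residue numbering, occupancy
1.00, pLDDT in the B-factor column); each written model gets a JSON score
sidecar ``{"iptm": ..., "plddt": ..., "seed": ..., "model_index": ...}``
mirroring prediction score files.  On reading, Calpha atoms are extracted
(altloc A preferred, insertion codes preserved in residue order) and chain
types are inferred from the charge composition (Glu-rich → acidic "A",
Lys/Arg-rich → basic "B") unless given explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from .synthetic import AssemblyModel

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_AA1 = {v: k for k, v in _AA3.items()}


def write_pdb(
    model: AssemblyModel,
    path: str | Path,
    sequence: str | None = None,
    sidecar: bool = True,
) -> None:
    """Write a Calpha-only model as PDB (plus a JSON score sidecar).

    ``sequence`` assigns residue names per chain position (GLY otherwise).
    The sidecar is written next to the PDB as ``<stem>_scores.json``.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.model_id or path.stem
    gm = gemmi.Model("1")
    plddt = float(model.scores.get("plddt", 0.0))
    for cid, _, xyz in model.chains:
        chain = gemmi.Chain(cid)
        for i, pos in enumerate(xyz):
            res = gemmi.Residue()
            res.name = _AA3.get(sequence[i], "GLY") if sequence else "GLY"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, pos))
            atom.occ = 1.0
            atom.b_iso = plddt
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
    if sidecar and model.scores:
        sc = {
            k: model.scores[k]
            for k in ("iptm", "plddt", "seed", "model_index")
            if k in model.scores
        }
        with open(path.with_name(path.stem + "_scores.json"), "w") as fh:
            json.dump(sc, fh, indent=1)


def _infer_chain_type(one_letter: str) -> str:
    acidic = sum(one_letter.count(a) for a in "DE")
    basic = sum(one_letter.count(b) for b in "KR")
    return "A" if acidic >= basic else "B"


def read_model(
    path: str | Path,
    scores_path: str | Path | None = None,
    chain_types: dict[str, str] | None = None,
) -> AssemblyModel:
    """Load an assembly model from PDB or mmCIF (Calpha extraction).

    Alternate locations prefer altloc 'A' (or blank); the first model of
    multi-model files is used.  Scores come from ``scores_path`` if given,
    else from a ``<stem>_scores.json`` sidecar when present (ColabFold-style
    ``*_scores.json`` naming is therefore picked up automatically).
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    gm = st[0]
    chains: list[tuple[str, str, np.ndarray]] = []
    seqs: list[str] = []
    for chain in gm:
        coords = []
        letters = []
        for res in chain:
            ca = None
            for atom in res:
                if atom.name == "CA" and (not atom.has_altloc() or atom.altloc == "A"):
                    ca = atom
                    break
            if ca is not None:
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
                letters.append(_AA1.get(res.name, "X"))
        if coords:
            chains.append((chain.name, "", np.array(coords)))
            seqs.append("".join(letters))
    if not chains:
        raise ValueError(f"no Calpha atoms found in {path}")
    typed = []
    for (cid, _, xyz), seq in zip(chains, seqs):
        ctype = (chain_types or {}).get(cid) or _infer_chain_type(seq)
        typed.append((cid, ctype, xyz))

    scores: dict = {}
    if scores_path is None:
        candidate = path.with_name(path.stem + "_scores.json")
        scores_path = candidate if candidate.exists() else None
    if scores_path is not None:
        with open(scores_path) as fh:
            raw = json.load(fh)
        for key in ("iptm", "plddt", "seed", "model_index"):
            if key in raw:
                scores[key] = raw[key]
        # ColabFold sidecars report per-residue pLDDT as a list
        if isinstance(scores.get("plddt"), list):
            scores["plddt"] = float(np.mean(scores["plddt"]))
    return AssemblyModel(
        chains=typed, scores=scores, provenance=str(path), model_id=path.stem
    )


def read_model_directory(directory: str | Path) -> list[AssemblyModel]:
    """Load every PDB/mmCIF model in a directory (with any score sidecars)."""
    directory = Path(directory)
    paths = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in (".pdb", ".cif", ".mmcif")
    )
    if not paths:
        raise FileNotFoundError(f"no PDB/mmCIF models in {directory}")
    return [read_model(p) for p in paths]
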