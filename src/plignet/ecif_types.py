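"""ECIF atom typing resources.

An ECIF atom type is the tuple (element, valence, heavy_degree, h_count,
is_aromatic, in_ring).  Protein atoms drawn from the 20 canonical amino
acids fall into exactly 22 such types; that table is packaged here as a
fixed, ordered resource because the radial environment vectors are indexed
by it (N = 22 fixes the vector length).

The per-residue templates below assign a type to every heavy atom of an
in-chain canonical residue, using physiological protonation and with the
delocalised charged groups (guanidinium, carboxylate) counted in their
all-double-bond representation:

* Lys NZ is protonated (valence 4, three H);
* Arg guanidinium: all three CZ-N bonds count as double, so CZ has
  valence 6, NE valence 4 with one H, NH1/NH2 valence 4 with two H;
* Asp/Glu carboxylate: both C-O bonds count as double, so the carbon has
  valence 5 and both oxygens valence 2 with no H;
* His is the N-epsilon-H tautomer.

Enumerating the templates under these conventions reproduces the published
22-type table exactly; backbone nitrogens are typed in-chain (two heavy
neighbours).  Atoms with no template entry (OXT, terminal variants,
non-standard residues, ions) are left untyped and flagged by the reader.
"""

from __future__ import annotations

ECIFToken = tuple[str, int, int, int, bool, bool]


def token_to_string(token: ECIFToken) -> str:
    e, v, d, h, ar, ri = token
    return f"{e};{v};{d};{h};{int(ar)};{int(ri)}"


def token_from_string(s: str) -> ECIFToken:
    e, v, d, h, ar, ri = s.split(";")
    return (e, int(v), int(d), int(h), bool(int(ar)), bool(int(ri)))


#: The 22 protein atom types, in the fixed order used to index AEVs.
ECIF_PROTEIN_TYPES: tuple[ECIFToken, ...] = tuple(
    token_from_string(s)
    for s in (
        "C;4;1;3;0;0",
        "C;4;2;1;1;1",
        "C;4;2;2;0;0",
        "C;4;2;2;0;1",
        "C;4;3;0;0;0",
        "C;4;3;0;1;1",
        "C;4;3;1;0;0",
        "C;4;3;1;0;1",
        "C;5;3;0;0;0",
        "C;6;3;0;0;0",
        "N;3;1;2;0;0",
        "N;3;2;0;1;1",
        "N;3;2;1;0;0",
        "N;3;2;1;1;1",
        "N;3;3;0;0;1",
        "N;4;1;2;0;0",
        "N;4;1;3;0;0",
        "N;4;2;1;0;0",
        "O;2;1;0;0;0",
        "O;2;1;1;0;0",
        "S;2;1;1;0;0",
        "S;2;2;0;0;0",
    )
)

N_PROTEIN_TYPES = len(ECIF_PROTEIN_TYPES)

PROTEIN_TYPE_INDEX: dict[ECIFToken, int] = {
    t: i for i, t in enumerate(ECIF_PROTEIN_TYPES)
}

# -- shorthand tokens used in the templates -------------------------------

_BB_N = token_from_string("N;3;2;1;0;0")  # amide N-H, in chain
_BB_CA = token_from_string("C;4;3;1;0;0")
_BB_C = token_from_string("C;4;3;0;0;0")  # carbonyl carbon
_BB_O = token_from_string("O;2;1;0;0;0")  # carbonyl oxygen
_CH3 = token_from_string("C;4;1;3;0;0")
_CH2 = token_from_string("C;4;2;2;0;0")
_CH2_RING = token_from_string("C;4;2;2;0;1")
_CH1 = token_from_string("C;4;3;1;0;0")
_C_AROM_H = token_from_string("C;4;2;1;1;1")
_C_AROM_J = token_from_string("C;4;3;0;1;1")  # ring junction / substituted
_C_CARBOXYL = token_from_string("C;5;3;0;0;0")
_C_GUANID = token_from_string("C;6;3;0;0;0")
_O_CARBONYL = _BB_O
_O_HYDROXYL = token_from_string("O;2;1;1;0;0")
_N_AMIDE_H2 = token_from_string("N;3;1;2;0;0")
_N_AROM = token_from_string("N;3;2;0;1;1")
_N_AROM_H = token_from_string("N;3;2;1;1;1")

_BACKBONE = {"N": _BB_N, "CA": _BB_CA, "C": _BB_C, "O": _BB_O}

_SIDECHAINS: dict[str, dict[str, str]] = {
    "ALA": {"CB": "C;4;1;3;0;0"},
    "ARG": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;2;2;0;0",
        "CD": "C;4;2;2;0;0",
        "NE": "N;4;2;1;0;0",
        "CZ": "C;6;3;0;0;0",
        "NH1": "N;4;1;2;0;0",
        "NH2": "N;4;1;2;0;0",
    },
    "ASN": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;0;0;0",
        "OD1": "O;2;1;0;0;0",
        "ND2": "N;3;1;2;0;0",
    },
    "ASP": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;5;3;0;0;0",
        "OD1": "O;2;1;0;0;0",
        "OD2": "O;2;1;0;0;0",
    },
    "CYS": {"CB": "C;4;2;2;0;0", "SG": "S;2;1;1;0;0"},
    "GLN": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;2;2;0;0",
        "CD": "C;4;3;0;0;0",
        "OE1": "O;2;1;0;0;0",
        "NE2": "N;3;1;2;0;0",
    },
    "GLU": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;2;2;0;0",
        "CD": "C;5;3;0;0;0",
        "OE1": "O;2;1;0;0;0",
        "OE2": "O;2;1;0;0;0",
    },
    "GLY": {},
    "HIS": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;0;1;1",
        "ND1": "N;3;2;0;1;1",
        "CD2": "C;4;2;1;1;1",
        "CE1": "C;4;2;1;1;1",
        "NE2": "N;3;2;1;1;1",
    },
    "ILE": {
        "CB": "C;4;3;1;0;0",
        "CG1": "C;4;2;2;0;0",
        "CG2": "C;4;1;3;0;0",
        "CD1": "C;4;1;3;0;0",
    },
    "LEU": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;1;0;0",
        "CD1": "C;4;1;3;0;0",
        "CD2": "C;4;1;3;0;0",
    },
    "LYS": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;2;2;0;0",
        "CD": "C;4;2;2;0;0",
        "CE": "C;4;2;2;0;0",
        "NZ": "N;4;1;3;0;0",
    },
    "MET": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;2;2;0;0",
        "SD": "S;2;2;0;0;0",
        "CE": "C;4;1;3;0;0",
    },
    "PHE": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;0;1;1",
        "CD1": "C;4;2;1;1;1",
        "CD2": "C;4;2;1;1;1",
        "CE1": "C;4;2;1;1;1",
        "CE2": "C;4;2;1;1;1",
        "CZ": "C;4;2;1;1;1",
    },
    "PRO": {
        "CB": "C;4;2;2;0;1",
        "CG": "C;4;2;2;0;1",
        "CD": "C;4;2;2;0;1",
    },
    "SER": {"CB": "C;4;2;2;0;0", "OG": "O;2;1;1;0;0"},
    "THR": {
        "CB": "C;4;3;1;0;0",
        "OG1": "O;2;1;1;0;0",
        "CG2": "C;4;1;3;0;0",
    },
    "TRP": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;0;1;1",
        "CD1": "C;4;2;1;1;1",
        "CD2": "C;4;3;0;1;1",
        "NE1": "N;3;2;1;1;1",
        "CE2": "C;4;3;0;1;1",
        "CE3": "C;4;2;1;1;1",
        "CZ2": "C;4;2;1;1;1",
        "CZ3": "C;4;2;1;1;1",
        "CH2": "C;4;2;1;1;1",
    },
    "TYR": {
        "CB": "C;4;2;2;0;0",
        "CG": "C;4;3;0;1;1",
        "CD1": "C;4;2;1;1;1",
        "CD2": "C;4;2;1;1;1",
        "CE1": "C;4;2;1;1;1",
        "CE2": "C;4;2;1;1;1",
        "CZ": "C;4;3;0;1;1",
        "OH": "O;2;1;1;0;0",
    },
    "VAL": {
        "CB": "C;4;3;1;0;0",
        "CG1": "C;4;1;3;0;0",
        "CG2": "C;4;1;3;0;0",
    },
}


def _build_templates() -> dict[tuple[str, str], ECIFToken]:
    templates: dict[tuple[str, str], ECIFToken] = {}
    for resname, side in _SIDECHAINS.items():
        for name, tok in _BACKBONE.items():
            templates[(resname, name)] = tok
        for name, s in side.items():
            templates[(resname, name)] = token_from_string(s)
    # residue-specific backbone corrections
    templates[("GLY", "CA")] = token_from_string("C;4;2;2;0;0")
    templates[("PRO", "N")] = token_from_string("N;3;3;0;0;1")
    templates[("PRO", "CA")] = token_from_string("C;4;3;1;0;1")
    return templates


#: (residue name, PDB atom name) -> ECIF token for in-chain canonical residues.
RESIDUE_TEMPLATES: dict[tuple[str, str], ECIFToken] = _build_templates()

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
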