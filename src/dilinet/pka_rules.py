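"""Bundled pKa substructure rule table for pH-7.0 protonation adjustment.

Each rule is (name, SMARTS, pKa, kind, site) where ``site`` is the index,
within the SMARTS match, of the atom that gains or loses the proton.
``kind`` is "acid" (deprotonated when pH > pKa) or "base" (protonated when
pH < pKa).  pKa values are textbook class values; the table is versioned so
results can be traced to it.
"""

from __future__ import annotations

PKA_TABLE_VERSION = "1.0"

# (name, smarts, pKa, kind, site index in match)
PKA_RULES: list[tuple[str, str, float, str, int]] = [
    # acids — deprotonate at pH 7 when pKa < 7
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H1]", -1.0, "acid", 3),
    ("sulfinic_acid", "[SX3](=O)[OX2H1]", 2.0, "acid", 2),
    ("phosphonic_acid", "[PX4](=O)([OX2H1])[OX2H1]", 2.0, "acid", 2),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 4.8, "acid", 2),
    ("tetrazole", "[nX3H1]1nnnc1", 4.9, "acid", 0),
    ("arylsulfonamide", "[SX4](=O)(=O)[NX3H1]c", 10.1, "acid", 3),
    ("phenol", "c[OX2H1]", 10.0, "acid", 1),
    ("thiol", "[CX4][SX2H1]", 10.6, "acid", 1),
    # bases — protonate at pH 7 when pKa > 7
    ("guanidine", "[NX3][CX3](=[NX2;+0])[NX3]", 13.6, "base", 2),
    ("amidine", "[NX3][CX3;!$(C(N)N)]=[NX2;+0;!$(N-[#8]);!$(N-a)]", 12.4, "base", 2),
    (
        "aliphatic_amine",
        "[NX3;H2,H1,H0;+0;!$(N-C=[O,N,S]);!$(N-[SX4]);!$(N-a);!$(N=*);!$(N-[#8]);!$(N-n)]",
        10.7,
        "base",
        0,
    ),
    ("pyridine", "[nX2;+0]", 5.2, "base", 0),
    ("aniline", "[NX3;H2,H1;+0;$(N-a);!$(N-C=[O,N,S])]", 4.6, "base", 0),
]
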