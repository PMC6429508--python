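"""Curated GAG-binding-site declarations for the six study proteins.

Residue numbers are author numbers of the conventional human template
structures (antithrombin 1azx, heparanase 5E9C, CCL5 5COY, eotaxin-1 1EOT,
IL-8 1IL8, PF4 1F9Q), as established by mutagenesis, NMR and co-crystal
studies of heparin/heparan-sulfate binding. Heparanase is a two-chain
heterodimer; residues of the 8 kDa subunit are tagged chain B and users
should remap chain ids to match their coordinate files.

These declarations are configuration data for runs on real structures; the
synthetic test families declare their own sites.
"""

from __future__ import annotations

from .conserve import BindingSite, SiteResidue


def _site(protein: str, triples: list[tuple[str, int, str]]) -> BindingSite:
    return BindingSite(protein=protein,
                       residues=[SiteResidue(c, n, l) for c, n, l in triples])


BINDING_SITES: dict[str, BindingSite] = {
    # Heparin pentasaccharide site on antithrombin III.
    "antithrombin": _site("antithrombin", [
        ("A", 46, "R"), ("A", 47, "R"),
        ("A", 121, "F"), ("A", 122, "F"),
        ("A", 125, "K"), ("A", 129, "R"),
        ("A", 132, "R"), ("A", 133, "K"),
        ("A", 136, "K"), ("A", 228, "K"),
        ("A", 235, "R"), ("A", 236, "K"),
        ("A", 275, "K"),
    ]),
    # Heparan-sulfate cleft of heparanase (catalytic E225/E343 included).
    "heparanase": _site("heparanase", [
        ("B", 62, "N"), ("B", 64, "N"), ("B", 97, "T"),
        ("A", 224, "N"), ("A", 225, "E"), ("A", 270, "Q"),
        ("A", 272, "R"), ("A", 343, "E"),
        ("A", 349, "G"), ("A", 350, "G"),
        ("A", 389, "G"), ("A", 391, "Y"),
    ]),
    # CCL5 (RANTES): Arg17 plus the 40s BBXB motif and the 50s motif.
    "ccl5": _site("ccl5", [
        ("A", 17, "R"),
        ("A", 44, "R"), ("A", 45, "K"), ("A", 46, "N"), ("A", 47, "R"),
        ("A", 55, "K"), ("A", 56, "K"), ("A", 57, "W"), ("A", 58, "V"),
        ("A", 59, "R"),
    ]),
    # Eotaxin-1 (CCL11): putative site by homology with CCL5.
    "eotaxin1": _site("eotaxin1", [
        ("A", 44, "K"), ("A", 45, "L"), ("A", 46, "A"), ("A", 47, "K"),
        ("A", 54, "K"), ("A", 55, "K"), ("A", 56, "K"),
    ]),
    # IL-8 (CXCL8) monomer GAG site.
    "il8": _site("il8", [
        ("A", 15, "K"), ("A", 18, "H"), ("A", 20, "K"), ("A", 23, "K"),
        ("A", 60, "R"), ("A", 64, "K"), ("A", 68, "R"),
    ]),
    # PF4 (CXCL4) ring-of-basic-residues site.
    "pf4": _site("pf4", [
        ("A", 20, "R"), ("A", 22, "R"), ("A", 23, "H"), ("A", 25, "T"),
        ("A", 46, "K"), ("A", 49, "R"),
        ("A", 60, "Y"), ("A", 61, "K"), ("A", 64, "I"), ("A", 65, "K"),
    ]),
}

# Default solve pH per protein: physiological for all but heparanase, which
# is active (and was analysed) at endosomal/lysosomal pH.
DEFAULT_PH: dict[str, float] = {name: 7.4 for name in BINDING_SITES}
DEFAULT_PH["heparanase"] = 5.5

# ESD comparison mode: large proteins restrict the comparison to the
# binding-site shell; the small chemokines are compared over the whole
# structure surface.
DEFAULT_MODE: dict[str, str] = {
    "antithrombin": "site-shell",
    "heparanase": "site-shell",
    "ccl5": "entire-structure",
    "eotaxin1": "entire-structure",
    "il8": "entire-structure",
    "pf4": "entire-structure",
}
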