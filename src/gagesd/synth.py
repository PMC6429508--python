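"""Synthetic homolog families with planted divergence.

Real cross-species comparisons start from orthologs downloaded from
sequence databases and homology models built on a shared template. This
module generates the same statistical structure fully in silico so every
downstream stage is testable against a known truth: an idealised α-helical
mini-protein template with one side-chain pseudo-atom per residue,
sequences diverged along a planted tree with separate substitution rates
for binding-site and background positions (optionally biased toward
charge-altering substitutions in the site), threaded structures, and a
:class:`FamilyTruth` record of every planted event.

Defaults emulate a small ortholog family: a 60-residue template with a
basic (K/R-rich) binding patch and a few scattered acidic residues, and
per-branch substitution probabilities of a few percent — the divergence
scale of the mammalian orthologs the analysis targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .align import PairwiseAlignment
from .conserve import BindingSite, SiteResidue
from .prep import thread_model
from .types import Atom, SequenceRecord, Structure

HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TURN = 100.0      # degrees per residue
HELIX_RADIUS = 2.3      # Å, Cα distance from the axis
SIDECHAIN_OFFSET = 2.5  # Å, pseudo-atom beyond the Cα radially

POSITIVE = "KRH"
NEGATIVE = "DE"
NEUTRAL = "ACFGILMNPQSTVWY"

DEFAULT_N_RES = 60
DEFAULT_SITE_POSITIONS = (24, 27, 30, 33, 36, 39)
DEFAULT_CHARGED = {24: "K", 27: "R", 30: "K", 33: "K", 36: "R", 39: "K",
                   6: "D", 12: "E", 48: "E", 54: "D"}


def default_site_positions(n_res: int) -> tuple[int, ...]:
    """Basic binding patch: every 3rd position across the middle sixth."""
    if n_res == DEFAULT_N_RES:
        return DEFAULT_SITE_POSITIONS
    mid = n_res // 2
    return tuple(mid + d for d in (-6, -3, 0, 3, 6))


def default_charged_positions(n_res: int) -> dict[int, str]:
    """K/R cluster at the site plus a couple of scattered acids."""
    if n_res == DEFAULT_N_RES:
        return dict(DEFAULT_CHARGED)
    pos = {p: "KRKRK"[i % 5]
           for i, p in enumerate(default_site_positions(n_res))}
    pos[max(2, n_res // 10)] = "D"
    pos[min(n_res - 1, 9 * n_res // 10)] = "E"
    return pos


def make_template(n_res: int = DEFAULT_N_RES,
                  charged_positions: dict[int, str] | None = None,
                  seed: int = 0, id: str = "template"
                  ) -> tuple[Structure, SequenceRecord]:
    """Ideal α-helix template with one side-chain pseudo-atom per residue.

    Cα atoms sit on a helix (1.5 Å rise, 100° turn, 2.3 Å radius); each
    residue's ``SC`` pseudo-atom sits 2.5 Å further out along the same
    radial direction. The sequence is alanine except at the requested
    charged positions (1-based). ``seed`` is accepted for API symmetry;
    the geometry is deterministic.
    """
    del seed
    if n_res < 10:
        raise ValueError("template needs at least 10 residues")
    charged_positions = dict(charged_positions if charged_positions is not None
                             else default_charged_positions(n_res))
    letters = ["A"] * n_res
    for pos, letter in charged_positions.items():
        if not 1 <= pos <= n_res:
            raise ValueError(f"charged position {pos} out of range 1..{n_res}")
        if letter not in POSITIVE + NEGATIVE:
            raise ValueError(f"position {pos}: {letter!r} is not a charged "
                             "residue letter (K/R/H/D/E)")
        letters[pos - 1] = letter
    seq = "".join(letters)

    from .types import ONE_TO_THREE
    atoms: list[Atom] = []
    for i, letter in enumerate(letters):
        theta = np.deg2rad(HELIX_TURN) * i
        z = HELIX_RISE * i
        cx, cy = np.cos(theta), np.sin(theta)
        name3 = ONE_TO_THREE[letter]
        atoms.append(Atom(name="CA", element="C", res_name=name3,
                          res_seq=i + 1, chain="A",
                          x=HELIX_RADIUS * cx, y=HELIX_RADIUS * cy, z=z))
        r_sc = HELIX_RADIUS + SIDECHAIN_OFFSET
        atoms.append(Atom(name="SC", element="C", res_name=name3,
                          res_seq=i + 1, chain="A",
                          x=r_sc * cx, y=r_sc * cy, z=z))
    record = SequenceRecord(id=id, residues=seq)
    return Structure(atoms, id=id), record


def make_binding_site(template: Structure, positions: list[int] | tuple,
                      protein: str = "synthetic") -> BindingSite:
    """Declare a binding site at 1-based template positions."""
    residues = template.residues()
    site = []
    for pos in positions:
        res = residues[pos - 1]
        site.append(SiteResidue(res.chain, res.res_seq, res.one_letter))
    return BindingSite(protein=protein, residues=site)


# ---------------------------------------------------------------------------
# Planted trees

@dataclass
class TreeNode:
    """A rooted planted tree with unit-length branches."""

    name: str
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        def _fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:1"
            inner = ",".join(_fmt(c) for c in node.children)
            return f"({inner}):1"
        inner = ",".join(_fmt(c) for c in self.children) if self.children \
            else self.name
        return f"({inner});" if self.children else f"{self.name};"

    def leaf_path_lengths(self) -> dict[tuple[str, str], int]:
        """Branch-count path length between every unordered leaf pair."""
        depths: dict[str, list[str]] = {}

        def _walk(node: TreeNode, path: list[str]) -> None:
            if node.is_leaf:
                depths[node.name] = path + [node.name]
            for c in node.children:
                _walk(c, path + [node.name])

        _walk(self, [])
        out: dict[tuple[str, str], int] = {}
        names = sorted(depths)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pa, pb = depths[a], depths[b]
                shared = 0
                for x, y in zip(pa, pb):
                    if x == y:
                        shared += 1
                    else:
                        break
                out[(a, b)] = (len(pa) - shared) + (len(pb) - shared)
        return out


def balanced_tree(n_leaves: int, prefix: str = "sp") -> TreeNode:
    """Balanced binary planted tree with leaves named sp1..spN.

    Odd level widths carry the unpaired subtree up a level, so any
    n_leaves >= 2 is accepted.
    """
    if n_leaves < 2:
        raise ValueError("planted tree needs at least 2 leaves")
    level: list[TreeNode] = [TreeNode(name=f"{prefix}{i + 1}")
                             for i in range(n_leaves)]
    counter = 0
    while len(level) > 1:
        nxt = []
        for i in range(0, len(level) - 1, 2):
            counter += 1
            nxt.append(TreeNode(name=f"n{counter}",
                                children=[level[i], level[i + 1]]))
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
    root = level[0]
    root.name = "root"
    return root


# ---------------------------------------------------------------------------
# Family evolution

@dataclass
class FamilyTruth:
    """Planted truth for one simulated family."""

    tree_newick: str
    seed: int
    site_positions: list[int]
    substitutions_site: dict[str, int] = field(default_factory=dict)
    substitutions_background: dict[str, int] = field(default_factory=dict)
    charge_flips_site: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "tree_newick": self.tree_newick,
            "seed": self.seed,
            "site_positions": self.site_positions,
            "substitutions_site": self.substitutions_site,
            "substitutions_background": self.substitutions_background,
            "charge_flips_site": self.charge_flips_site,
        }, indent=2, sort_keys=True)


def _charge_group(letter: str) -> str:
    if letter in POSITIVE:
        return "+"
    if letter in NEGATIVE:
        return "-"
    return "0"


def _conservative_substitute(letter: str, rng: np.random.Generator) -> str:
    group = {"+": POSITIVE, "-": NEGATIVE, "0": NEUTRAL}[_charge_group(letter)]
    choices = [c for c in group if c != letter]
    return choices[rng.integers(len(choices))]


def _charge_flip_substitute(letter: str, rng: np.random.Generator) -> str:
    group = _charge_group(letter)
    if group == "+":
        pool = NEGATIVE
    elif group == "-":
        pool = POSITIVE
    else:
        pool = POSITIVE + NEGATIVE
    return pool[rng.integers(len(pool))]


def evolve_family(template_seq: SequenceRecord, tree: TreeNode,
                  site_positions: list[int] | tuple = DEFAULT_SITE_POSITIONS,
                  rate_site: float = 0.0, rate_background: float = 0.02,
                  charge_flip_bias: float = 0.5, seed: int = 1
                  ) -> tuple[dict[str, SequenceRecord], FamilyTruth]:
    """Diverge the template along the planted tree.

    Each position mutates independently on each branch with its class rate
    (binding-site vs background). Site-class substitutions are
    charge-altering with probability ``charge_flip_bias`` and conservative
    (within the same charge group) otherwise; background substitutions are
    conservative. All events are recorded per leaf in the returned
    :class:`FamilyTruth`.
    """
    for r in (rate_site, rate_background, charge_flip_bias):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates and bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    site_set = set(site_positions)
    truth = FamilyTruth(tree_newick=tree.to_newick(), seed=seed,
                        site_positions=sorted(site_set))
    leaves: dict[str, SequenceRecord] = {}

    def _walk(node: TreeNode, seq: list[str],
              counts: tuple[int, int, int]) -> None:
        n_site, n_bg, n_flip = counts
        for child in node.children:
            child_seq = list(seq)
            c_site, c_bg, c_flip = n_site, n_bg, n_flip
            for pos in range(1, len(child_seq) + 1):
                in_site = pos in site_set
                rate = rate_site if in_site else rate_background
                if rate == 0.0 or rng.random() >= rate:
                    continue
                old = child_seq[pos - 1]
                if in_site and rng.random() < charge_flip_bias:
                    new = _charge_flip_substitute(old, rng)
                    c_flip += 1
                else:
                    new = _conservative_substitute(old, rng)
                child_seq[pos - 1] = new
                if in_site:
                    c_site += 1
                else:
                    c_bg += 1
            if child.is_leaf:
                leaves[child.name] = SequenceRecord(
                    id=child.name, residues="".join(child_seq))
                truth.substitutions_site[child.name] = c_site
                truth.substitutions_background[child.name] = c_bg
                truth.charge_flips_site[child.name] = c_flip
            else:
                _walk(child, child_seq, (c_site, c_bg, c_flip))

    _walk(tree, list(template_seq.residues), (0, 0, 0))
    return leaves, truth


def make_flip_family(template_seq: SequenceRecord,
                     site_positions: list[int] | tuple,
                     flip_counts: dict[str, int], seed: int = 1
                     ) -> tuple[dict[str, SequenceRecord], FamilyTruth]:
    """Plant exact numbers of charge-reversing substitutions per species.

    Species ``s`` receives ``flip_counts[s]`` charge flips at randomly
    chosen charged site positions (sampling is per species with a shared
    seed, so the flipped sets are nested-free but reproducible).
    """
    rng = np.random.default_rng(seed)
    charged_site = [p for p in sorted(set(site_positions))
                    if _charge_group(template_seq.residues[p - 1]) != "0"]
    max_flips = max(flip_counts.values(), default=0)
    if max_flips > len(charged_site):
        raise ValueError("more flips requested than charged site positions")
    truth = FamilyTruth(tree_newick="", seed=seed,
                        site_positions=sorted(set(site_positions)))
    out: dict[str, SequenceRecord] = {}
    for species, k in flip_counts.items():
        seq = list(template_seq.residues)
        chosen = rng.permutation(len(charged_site))[:k]
        for idx in sorted(chosen):
            pos = charged_site[idx]
            seq[pos - 1] = _charge_flip_substitute(seq[pos - 1], rng)
        out[species] = SequenceRecord(id=species, residues="".join(seq))
        truth.substitutions_site[species] = k
        truth.substitutions_background[species] = 0
        truth.charge_flips_site[species] = k
    return out, truth


def realize_structures(template: Structure, template_seq: SequenceRecord,
                       sequences: dict[str, SequenceRecord]
                       ) -> dict[str, Structure]:
    """Thread every family member onto the template backbone.

    Family sequences are equal-length with the template by construction,
    so the guiding alignment is gap-free.
    """
    out: dict[str, Structure] = {}
    for name, rec in sequences.items():
        if len(rec) != len(template_seq):
            raise ValueError(f"sequence {name!r} is not template-length")
        aln = PairwiseAlignment(template_seq.id, rec.id,
                                template_seq.residues, rec.residues,
                                score=0.0)
        out[name] = thread_model(template, template_seq, rec, aln)
    return out
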