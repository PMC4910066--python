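"""Duplication–divergence simulator: ground truth for the repeat clock.

The generative model mirrors the biology the indicator assumes: a
prototype sequence is duplicated in tandem at time 0 (creating the
EA-gene, whose two repeat copies are identical), after which the gene is
inherited down a species tree and the two copies accumulate substitutions
independently under a reversible nucleotide model. A species whose
root-to-tip path carries mu*t expected substitutions/site per copy has
true repeat divergence 2*mu*t — exactly the quantity d_DR estimates.

Two perturbations exercise the applicability criteria and the
emergence-order analysis: an optional re-duplication on one lineage
(overwriting the second copy with the first, which breaks the
single-duplication bipartition), and a stem offset Delta that lets a
second gene family start diverging earlier, displacing its true d_DR by
2*Delta on every species.

Substitutions are simulated exactly by per-site Poisson event counts
under the uniformized jump kernel of the rate matrix (no time
discretization).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import TreeNode

from ddrclock.distances import tn93_rate_matrix
from ddrclock.phylo import read_newick, write_newick
from ddrclock.repeatio import (
    AlignmentSet,
    RepeatPair,
    SeqRecordNT,
    alignment_set_from_pairs,
    write_fasta,
    write_metadata,
)

_BASES = np.array(list("ACGT"))

#: default repeat length in sites, echoing the TFIIB comparison size
DEFAULT_REPEAT_LENGTH = 282


@dataclass(frozen=True)
class SubstitutionModel:
    """A scaled reversible rate matrix (one expected sub/site/unit time)."""

    name: str
    Q: np.ndarray
    pi: np.ndarray

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        pi = np.full(4, 0.25)
        return cls("jc69", tn93_rate_matrix(pi, 1.0, 1.0), pi)

    @classmethod
    def k2p(cls, kappa: float = 2.0) -> "SubstitutionModel":
        pi = np.full(4, 0.25)
        return cls("k2p", tn93_rate_matrix(pi, kappa, kappa), pi)

    @classmethod
    def tn93(
        cls,
        kappa1: float = 2.0,
        kappa2: float = 4.0,
        pi: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "SubstitutionModel":
        pi = np.asarray(pi, dtype=float)
        return cls("tn93", tn93_rate_matrix(pi, kappa1, kappa2), pi)


def as_substitution_model(spec) -> SubstitutionModel:
    if isinstance(spec, SubstitutionModel):
        return spec
    if isinstance(spec, str):
        if spec == "jc69":
            return SubstitutionModel.jc69()
        if spec == "k2p":
            return SubstitutionModel.k2p()
        if spec == "tn93":
            return SubstitutionModel.tn93()
        raise ValueError(f"unknown substitution model {spec!r}")
    name, *params = spec
    if name == "k2p":
        return SubstitutionModel.k2p(*params)
    if name == "tn93":
        return SubstitutionModel.tn93(*params)
    raise ValueError(f"unknown substitution model spec {spec!r}")


def _evolve(
    states: np.ndarray, t: float, model: SubstitutionModel, rng: np.random.Generator
) -> np.ndarray:
    """Evolve integer-coded sites for branch length t (subs/site).

    Uniformization: events per site ~ Poisson(lambda*t) with
    lambda = max total leaving rate; each event applies the jump kernel
    K = I + Q/lambda (self-transitions allowed). Exact for any t.
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if t == 0:
        return states.copy()
    lam = float(np.max(-np.diag(model.Q)))
    K = np.eye(4) + model.Q / lam
    k = rng.poisson(lam * t, size=states.size)
    out = states.copy()
    for kv in np.unique(k):
        if kv == 0:
            continue
        P = np.linalg.matrix_power(K, int(kv))
        mask = k == kv
        probs = P[states[mask]]
        u = rng.random(mask.sum())
        out[mask] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return out


def yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> TreeNode:
    """Seeded pure-birth species tree with branch lengths in time units."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=None)
    birth: dict[int, float] = {id(root): 0.0}
    active: list[TreeNode] = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.length = (
            None if node is root else t - birth[id(node)]
        )
        kids = [TreeNode(length=None), TreeNode(length=None)]
        for kid in kids:
            birth[id(kid)] = t
            node.append(kid)
        active.extend(kids)
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i, node in enumerate(active):
        node.length = present - birth[id(node)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"s{i + 1}"
    return root


def star_tree(n_tips: int, branch_length: float) -> TreeNode:
    """n species all diverging at the root, each at the given depth."""
    root = TreeNode()
    for i in range(n_tips):
        root.append(TreeNode(name=f"s{i + 1}", length=branch_length))
    return root


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated repeat family.

    ``species_tree`` may be a Newick string or TreeNode whose branch
    lengths are expected substitutions/site per repeat copy (mu*t); when
    absent, a star tree of ``n_species`` tips at depth ``mu_t`` is used.
    ``stem_offset`` is the divergence accumulated between the founding
    duplication and the species-tree root (each copy evolves that extra
    length, so true d_DR grows by 2*stem_offset everywhere). It defaults
    to 0.1: the single-duplication topology test is only meaningful when
    the duplication predates the radiation, since the stem is exactly the
    edge that separates the first-repeat clade from the second-repeat
    clade. Set it to 0 to model duplication at the radiation itself.
    ``second_duplication`` names a tip whose second copy is overwritten by
    its first at the start of its terminal branch.
    """

    seed: int = 0
    repeat_length: int = DEFAULT_REPEAT_LENGTH
    model: object = "jc69"
    species_tree: object = None
    n_species: int = 8
    mu_t: float = 0.25
    stem_offset: float = 0.1
    second_duplication: str | None = None

    def resolve_tree(self) -> TreeNode:
        st = self.species_tree
        if st is None:
            return star_tree(self.n_species, self.mu_t)
        if isinstance(st, TreeNode):
            return st
        return read_newick(str(st))


@dataclass
class SimResult:
    """Simulated repeat pairs plus the generating truth.

    ``true_ddr`` maps each species to its expected repeat divergence
    (2 x substitutions/site accumulated per copy since the relevant
    duplication); ``config`` echoes the generating conditions.
    """

    pairs: list[RepeatPair]
    true_ddr: dict[str, float]
    tree: TreeNode
    config: SimConfig

    def to_alignment_set(self) -> AlignmentSet:
        return alignment_set_from_pairs(self.pairs)

    def write(self, outdir: "str | Path") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aln = self.to_alignment_set()
        write_fasta(aln.records, outdir / "repeats.fasta")
        write_metadata(aln.metadata, outdir / "metadata.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(f"# seed={self.config.seed}\n")
            fh.write("species\ttrue_ddr\n")
            for sp, v in sorted(self.true_ddr.items()):
                fh.write(f"{sp}\t{v:.6g}\n")
        with open(outdir / "species_tree.nwk", "w") as fh:
            fh.write(write_newick(self.tree) + "\n")


def simulate_family(cfg: SimConfig) -> SimResult:
    """Simulate one repeat family down the species tree.

    Deterministic given the config (including seed). With zero divergence
    everywhere, every pair comes out identical (the EA-gene case).
    """
    model = as_substitution_model(cfg.model)
    tree = cfg.resolve_tree()
    rng = np.random.default_rng(cfg.seed)
    proto = rng.choice(4, size=cfg.repeat_length, p=model.pi)
    # the gene carries both copies from the duplication (stem) onward
    first0 = _evolve(proto, cfg.stem_offset, model, rng)
    second0 = _evolve(proto, cfg.stem_offset, model, rng)

    pairs: list[RepeatPair] = []
    true_ddr: dict[str, float] = {}

    def descend(node: TreeNode, first: np.ndarray, second: np.ndarray, depth: float, reset_depth: float | None):
        for child in node.children:
            t = float(child.length or 0.0)
            f, s = first, second
            rd = reset_depth
            if child.is_tip() and child.name == cfg.second_duplication:
                s = f  # re-duplication: second copy overwritten
                rd = depth
            f2 = _evolve(f, t, model, rng)
            s2 = _evolve(s, t, model, rng)
            if child.is_tip():
                name = child.name
                seq_f = "".join(_BASES[f2])
                seq_s = "".join(_BASES[s2])
                pairs.append(
                    RepeatPair(
                        gene_id=name,
                        species=name,
                        domain="unknown",
                        first=SeqRecordNT(id=f"{name}__first", seq=seq_f),
                        second=SeqRecordNT(id=f"{name}__second", seq=seq_s),
                    )
                )
                if rd is None:
                    true_ddr[name] = 2.0 * (cfg.stem_offset + depth + t)
                else:
                    true_ddr[name] = 2.0 * (depth + t - rd)
            else:
                descend(child, f2, s2, depth + t, rd)

    descend(tree, first0, second0, 0.0, None)
    if cfg.second_duplication is not None and cfg.second_duplication not in true_ddr:
        raise ValueError(
            f"second_duplication lineage {cfg.second_duplication!r} "
            "is not a tip of the species tree"
        )
    return SimResult(pairs=pairs, true_ddr=true_ddr, tree=tree, config=cfg)


def simulate_two_families(
    cfg_a: SimConfig, delta: float, seed_b: "int | None" = None
) -> tuple[SimResult, SimResult]:
    """Two families on one species tree, family B duplicated earlier.

    Family B receives an extra stem divergence ``delta`` (per copy), so
    its true d_DR exceeds family A's by 2*delta on every species while
    post-speciation rates are identical — the slope ~ 1, positive-
    intercept regime of the emergence-order analysis.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    tree = cfg_a.resolve_tree()
    cfg_a = dataclasses.replace(cfg_a, species_tree=tree)
    cfg_b = dataclasses.replace(
        cfg_a,
        species_tree=tree,
        stem_offset=cfg_a.stem_offset + delta,
        seed=cfg_a.seed + 1 if seed_b is None else seed_b,
    )
    return simulate_family(cfg_a), simulate_family(cfg_b)


def random_pair_identity(
    length: int,
    replicates: int = 10,
    seed: int = 0,
    freqs: "Sequence[float] | None" = None,
) -> float:
    """Mean percent identity between i.i.d. random nucleotide pairs.

    With uniform composition the expectation is 25% — the floor below
    which repeat similarity is indistinguishable from noise. Biased
    composition raises the floor to sum(f_i^2).
    """
    if length < 1 or replicates < 1:
        raise ValueError("length and replicates must be positive")
    rng = np.random.default_rng(seed)
    p = None if freqs is None else np.asarray(freqs, dtype=float)
    matches = np.empty(replicates)
    for r in range(replicates):
        a = rng.choice(4, size=length, p=p)
        b = rng.choice(4, size=length, p=p)
        matches[r] = (a == b).mean()
    return float(matches.mean() * 100.0)
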