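"""The repeat-divergence clock: d_DR computation, criteria, ranking.

d_DR is the evolutionary distance (substitutions/site) between the first
and second repeat copies inside a single gene. Because the two copies were
identical at the moment the gene was created by tandem duplication (the
EA-gene), d_DR estimates the distance from that common origin to each
present-day gene — with no outer group required. The estimate is valid
only when (1) the family descends from a single duplication event, tested
on the joint repeat tree, and (2) repeat identity sits clearly above the
~25% random-match floor for nucleotide sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ddrclock.distances import (
    ComparisonError,
    DistanceModel,
    as_model,
    compare_pair,
    distance,
    distance_matrix,
    fit_mcl,
    mcl_distances,
)
from ddrclock.phylo import DuplicationTestResult, duplication_once_test
from ddrclock.repeatio import AlignmentSet, RepeatPair, alignment_set_from_pairs

DEFAULT_IDENTITY_THRESHOLD = 30.0  # percent; above the 25% random floor


class CriterionError(ValueError):
    """Invalid criterion configuration."""


def check_criterion2(
    identity_pct: float, threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> bool:
    """Conservation-ratio criterion: identity must clear the random floor.

    Two random unbiased nucleotide sequences agree at ~25% of sites, so
    divergence is only measurable when repeat identity sits comfortably
    above that; the default cutoff is 30%. Thresholds at or below the 25%
    floor (or above 100) are rejected as meaningless.
    """
    if not 0.0 <= identity_pct <= 100.0:
        raise CriterionError(f"identity_pct out of range: {identity_pct}")
    if not 25.0 < threshold <= 100.0:
        raise CriterionError(
            f"threshold must be in (25, 100], got {threshold}"
        )
    return identity_pct >= threshold


def criterion2_permutation(
    pair: RepeatPair,
    replicates: int = 200,
    seed: int = 0,
    percentile: float = 99.0,
) -> bool:
    """Permutation variant of criterion 2 for borderline identities.

    Shuffles the comparable columns of the second repeat ``replicates``
    times; passes iff the observed identity exceeds the given percentile
    of the shuffled null. Conditions on the pair's own base composition,
    so a compositional-bias-inflated identity does not pass spuriously.
    """
    rng = np.random.default_rng(seed)
    a = np.frombuffer(pair.first.seq.encode(), dtype="S1")
    b = np.frombuffer(pair.second.seq.encode(), dtype="S1")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    bases = np.isin(a, acgt) & np.isin(b, acgt)
    if not bases.any():
        raise ComparisonError("no comparable sites")
    x, y = a[bases], b[bases]
    observed = float((x == y).mean())
    null = np.empty(replicates)
    for r in range(replicates):
        null[r] = (x == rng.permutation(y)).mean()
    return observed > float(np.percentile(null, percentile))


@dataclass(frozen=True)
class DdrResult:
    """Per-gene repeat comparison: identity counts, d_DR, criteria flags."""

    gene_id: str
    species: str
    domain: str
    identical: int
    compared: int
    identity_pct: float
    ddr: float
    model: DistanceModel
    criterion1: DuplicationTestResult | None = None
    criterion2_pass: bool = True

    @property
    def saturated(self) -> bool:
        return not math.isfinite(self.ddr)

    @property
    def passes_criteria(self) -> bool:
        c1 = self.criterion1.passed if self.criterion1 is not None else True
        return c1 and self.criterion2_pass and not self.saturated


def compute_ddr(
    pair: RepeatPair,
    model: "DistanceModel | str" = "mcl_composite",
    aln_context: "AlignmentSet | None" = None,
    criterion1: DuplicationTestResult | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> DdrResult:
    """Compute one gene's d_DR and evaluate its applicability criteria.

    Identical repeats give d_DR = 0 under every model (the EA-gene zero
    point). A saturated distance is reported flagged rather than capped.
    """
    model = as_model(model)
    cmp_ = compare_pair(pair.first, pair.second)
    ddr = distance(pair.first, pair.second, model, aln_context=aln_context)
    return DdrResult(
        gene_id=pair.gene_id,
        species=pair.species,
        domain=pair.domain,
        identical=cmp_.identical,
        compared=cmp_.compared,
        identity_pct=cmp_.identity_pct,
        ddr=ddr,
        model=model,
        criterion1=criterion1,
        criterion2_pass=check_criterion2(cmp_.identity_pct, identity_threshold),
    )


@dataclass
class DdrTable:
    """Ranked per-gene d_DR report for one gene family.

    ``results`` is sorted ascending by d_DR (ties broken by species
    label); genes failing either criterion are kept in ``excluded`` with
    their flags, never silently dropped.
    """

    family: str
    results: list[DdrResult] = field(default_factory=list)
    excluded: list[DdrResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.results.sort(key=lambda r: (r.ddr, r.species))

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.results]

    @property
    def ddr_values(self) -> np.ndarray:
        return np.array([r.ddr for r in self.results])

    def domain_summary(self) -> dict[str, tuple[float, float]]:
        """Min/max d_DR per domain group among ranked entries."""
        out: dict[str, tuple[float, float]] = {}
        for r in self.results:
            lo, hi = out.get(r.domain, (math.inf, -math.inf))
            out[r.domain] = (min(lo, r.ddr), max(hi, r.ddr))
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for r in self.results + self.excluded:
            rows.append(
                {
                    "species": r.species,
                    "gene": r.gene_id,
                    "identical": r.identical,
                    "compared": r.compared,
                    "identity_pct": r.identity_pct,
                    "ddr": r.ddr,
                    "domain": r.domain,
                    "criterion1_pass": (
                        r.criterion1.passed if r.criterion1 else None
                    ),
                    "criterion2_pass": r.criterion2_pass,
                    "ranked": r in self.results,
                }
            )
        return rows

    def write_tsv(self, path: str | Path, provenance: str = "") -> None:
        rows = self.to_rows()
        cols = list(rows[0]) if rows else []
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write(f"# family: {self.family}\n")
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    def to_json(self, provenance: str = "") -> str:
        return json.dumps(
            {
                "family": self.family,
                "provenance": provenance,
                "rows": self.to_rows(),
            },
            indent=2,
        )


def rank_table(results: Iterable[DdrResult], family: str = "") -> DdrTable:
    """Rank genes by ascending d_DR; criterion failures are set aside.

    All results must share one distance model (mixing families/models
    would make the ranking meaningless).
    """
    results = list(results)
    if not results:
        raise ValueError("no results to rank")
    models = {r.model.name for r in results}
    if len(models) > 1:
        raise ValueError(f"mixed distance models in one ranking: {models}")
    kept = [r for r in results if r.passes_criteria]
    dropped = [r for r in results if not r.passes_criteria]
    return DdrTable(family=family, results=kept, excluded=dropped)


def analyze_family(
    pairs: Sequence[RepeatPair],
    model: "DistanceModel | str" = "mcl_composite",
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    family: str = "",
    run_criterion1: bool = True,
) -> DdrTable:
    """Full per-family pipeline: joint repeat tree test, per-gene d_DR,
    criteria gating, ranking."""
    model = as_model(model)
    aln = alignment_set_from_pairs(pairs)
    c1 = duplication_once_test(aln, model) if run_criterion1 else None
    results = []
    if model.name == "mcl_composite":
        # fit shared rates once over the whole family alignment
        seqs = [r.seq for r in aln.records]
        params = fit_mcl(seqs)
        idx = {rid: i for i, rid in enumerate(aln.ids)}
        pair_idx = [
            (idx[f"{p.gene_id}__r1"], idx[f"{p.gene_id}__r2"]) for p in pairs
        ]
        dvals = mcl_distances(seqs, pair_idx, params)
        for p, d in zip(pairs, dvals):
            cmp_ = compare_pair(p.first, p.second)
            results.append(
                DdrResult(
                    gene_id=p.gene_id,
                    species=p.species,
                    domain=p.domain,
                    identical=cmp_.identical,
                    compared=cmp_.compared,
                    identity_pct=cmp_.identity_pct,
                    ddr=float(d),
                    model=model,
                    criterion1=c1,
                    criterion2_pass=check_criterion2(
                        cmp_.identity_pct, identity_threshold
                    ),
                )
            )
    else:
        for p in pairs:
            results.append(
                compute_ddr(
                    p,
                    model,
                    criterion1=c1,
                    identity_threshold=identity_threshold,
                )
            )
    return rank_table(results, family=family)


@dataclass(frozen=True)
class ReferenceDistances:
    """Conventional between-gene distances from one reference species.

    The analog of measuring every gene against the M. jannaschii ortholog
    (d_Mj): an ordinary molecular-clock distance used as an external
    consistency check on the repeat-divergence clock.
    """

    reference: str
    distances: dict[str, float]

    def __post_init__(self) -> None:
        if not math.isclose(self.distances.get(self.reference, 0.0), 0.0):
            raise ValueError("self-distance must be 0")


def reference_distances(
    aln: AlignmentSet,
    reference_id: str,
    model: "DistanceModel | str" = "mcl_composite",
) -> ReferenceDistances:
    """Distance from a reference sequence to every other sequence."""
    if reference_id not in aln.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    dm = distance_matrix(aln, model)
    i = dm.labels.index(reference_id)
    dists = {
        label: float(dm.values[i, j]) for j, label in enumerate(dm.labels)
    }
    return ReferenceDistances(reference=reference_id, distances=dists)
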