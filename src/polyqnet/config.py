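"""Analysis configuration.

All scalar thresholds of the pipeline live in one dataclass so that every
stage reads the same values and a run is fully described by (inputs, config,
seed).  The defaults encode the published analysis choices: a strict
co-expression cutoff of r > 0.5, two one-tailed Mann-Whitney tests at
alpha = 0.025 per tail with a 5-of-6 donor consensus, one-tailed Fisher
overlap tests at p < 0.05, a functional-overlap floor of 10 shared terms,
and Benjamini-Hochberg-adjusted enrichment at 0.05 with at least two query
genes per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

#: The nine genes whose CAG-repeat expansions cause polyglutamine diseases.
POLYQ_GENES: tuple[str, ...] = (
    "HTT",
    "ATXN1",
    "ATXN2",
    "ATXN3",
    "CACNA1A",
    "ATXN7",
    "TBP",
    "ATN1",
    "AR",
)


@dataclass
class AnalysisConfig:
    """Scalar thresholds and switches for the whole pipeline.

    Parameters
    ----------
    coexpr_threshold
        Consensus Pearson r above which (strictly) two genes are called
        co-expressed.
    de_alpha
        Per-tail significance level of the one-tailed Mann-Whitney tests.
    min_brains
        Number of donors that must be significant in the same tail for a
        consensus differential-expression call.
    n_brains
        Number of donors in the dataset.
    fisher_alpha
        Significance level for the one-tailed Fisher partner-overlap test.
    min_shared_terms
        Minimum number of shared enriched terms for a functional overlap.
    enrich_alpha
        Benjamini-Hochberg adjusted significance level for term enrichment.
    min_genes_per_term
        Minimum number of query genes in a term for it to pass.
    min_region_samples
        Donors contribute to a region only with at least this many samples
        there (Pearson r is undefined below 3 points).
    polyq_genes
        Gene symbols of the nine polyglutamine genes, matched case-sensitively.
    rng_seed
        Seed for every stochastic step.
    mw_exact_cap
        Exact Mann-Whitney enumeration is used when the two group sizes sum
        to at most this and there are no ties; otherwise the normal
        approximation with tie and continuity corrections.
    bonferroni_de
        Optional per-donor Bonferroni mode: divide ``de_alpha`` by the gene
        count before the per-donor significance calls.
    fisher_z_consensus
        Average donor correlations on the Fisher z scale instead of plain r.
    connectivity_absolute
        Sum |r| instead of signed r in the probe connectivity score.
    connectivity_scope
        ``"other_genes"`` (default) sums correlations against probes of other
        genes only; ``"all_probes"`` includes sibling probes of the same gene.
    exclude_pair_from_partner_sets
        Drop the two tested polyQ genes from each other's partner sets and
        from the Fisher background universe.
    bh_over_pairs
        Optionally Benjamini-Hochberg-adjust the 36 pairwise Fisher p-values.
    """

    coexpr_threshold: float = 0.5
    de_alpha: float = 0.025
    min_brains: int = 5
    n_brains: int = 6
    fisher_alpha: float = 0.05
    min_shared_terms: int = 10
    enrich_alpha: float = 0.05
    min_genes_per_term: int = 2
    min_region_samples: int = 3
    polyq_genes: tuple[str, ...] = POLYQ_GENES
    rng_seed: int = 0
    mw_exact_cap: int = 12
    bonferroni_de: bool = False
    fisher_z_consensus: bool = False
    connectivity_absolute: bool = False
    connectivity_scope: str = "other_genes"
    exclude_pair_from_partner_sets: bool = True
    bh_over_pairs: bool = False

    def __post_init__(self) -> None:
        self.polyq_genes = tuple(self.polyq_genes)
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.coexpr_threshold < 1.0:
            raise ValueError(
                f"coexpr_threshold must be in (0, 1), got {self.coexpr_threshold}"
            )
        if not 0.0 < self.de_alpha < 0.5:
            raise ValueError(f"de_alpha must be in (0, 0.5), got {self.de_alpha}")
        if self.min_brains > self.n_brains:
            raise ValueError(
                f"min_brains ({self.min_brains}) exceeds n_brains ({self.n_brains})"
            )
        if len(set(self.polyq_genes)) != 9:
            raise ValueError("polyq_genes must contain 9 unique symbols")
        if self.connectivity_scope not in ("other_genes", "all_probes"):
            raise ValueError(
                "connectivity_scope must be 'other_genes' or 'all_probes', "
                f"got {self.connectivity_scope!r}"
            )
        if self.min_region_samples < 3:
            raise ValueError("min_region_samples must be >= 3")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["polyq_genes"] = list(self.polyq_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)
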