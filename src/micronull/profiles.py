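"""Community-profile tables: reading, rank collapsing and per-site summaries.

Handles the shotgun-metagenomics "community profile" dialect used by the
Human Microbiome Project: a tab-delimited matrix whose first column holds
taxonomic lineage strings (rank-prefixed components joined by ``|`` or ``;``,
e.g. ``k__Bacteria|p__Firmicutes|...|g__Lactobacillus``) and whose remaining
columns hold per-sample relative abundances.  Such tables typically carry
rows at several taxonomic ranks at once (each rank's rows summing to 1 per
sample); analyses here collapse to a single rank (genus by default) before
computing diversities.

A synthetic generator emits fixtures in exactly this dialect — per-body-site
sample x genus matrices with Dirichlet structure — so the empirical pipeline
is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import alpha_diversity, gamma_diversity, pairwise_bray_curtis

__all__ = [
    "RANKS",
    "AbundanceTable",
    "BodySiteSummary",
    "read_profile_table",
    "write_profile_table",
    "lineage_rank",
    "collapse_to_rank",
    "deduplicate_subjects",
    "site_diversity_summary",
    "summarize_sites",
    "generate_synthetic_profile",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNCLASSIFIED = "unclassified"


@dataclass
class AbundanceTable:
    """Taxon-lineage x sample matrix of (relative) abundances."""

    taxon_lineages: list[str]
    sample_ids: list[str]
    values: np.ndarray
    rank: str = "mixed"
    delimiter: str = "|"
    sample_sites: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxon_lineages), len(self.sample_ids)):
            raise ValueError("values shape must be (num taxa, num samples)")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")

    def sample_matrix(self) -> np.ndarray:
        """Samples-as-rows matrix for the diversity functions."""
        return self.values.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.taxon_lineages, columns=self.sample_ids
        )


@dataclass(frozen=True)
class BodySiteSummary:
    """Per-body-site diversity summary (one output table row)."""

    site: str
    alpha_mean: float
    alpha_sd: float
    gamma: float
    beta_mean: float
    beta_sd: float
    n_samples: int


def _split_lineage(lineage: str, delimiter: str) -> list[str]:
    return [part for part in lineage.split(delimiter) if part != ""]


def lineage_rank(lineage: str, delimiter: str = "|") -> str:
    """Taxonomic rank of a lineage string's deepest component.

    Uses the rank prefix (``g__`` etc.) of the last component when present,
    otherwise falls back to positional depth (kingdom first).
    """
    parts = _split_lineage(lineage, delimiter)
    if not parts:
        raise ValueError("empty lineage string")
    last = parts[-1]
    for prefix, rank in zip(_PREFIXES, RANKS):
        if last.startswith(prefix):
            return rank
    if len(parts) > len(RANKS):
        raise ValueError(f"lineage deeper than {len(RANKS)} ranks: {lineage!r}")
    return RANKS[len(parts) - 1]


def _detect_delimiter(lineages: list[str]) -> str:
    pipe = sum("|" in s for s in lineages)
    semi = sum(";" in s for s in lineages)
    return ";" if semi > pipe else "|"


def read_profile_table(path: str | Path) -> AbundanceTable:
    """Parse a tab-delimited community-profile table.

    The first column holds lineage strings; remaining columns are numeric
    per-sample abundances.  Malformed cells are rejected with row/column
    coordinates; ragged rows, a missing header and negative values are
    errors.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty profile table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: header must name at least one sample column")
    sample_ids = header[1:]
    lineages: list[str] = []
    rows: list[list[float]] = []
    for row_num, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: row {row_num} has {len(cells)} fields, "
                f"expected {len(header)}"
            )
        lineages.append(cells[0])
        parsed: list[float] = []
        for col_num, cell in enumerate(cells[1:], start=2):
            try:
                value = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed numeric cell at row {row_num}, "
                    f"column {col_num}: {cell!r}"
                ) from exc
            if value < 0:
                raise ValueError(
                    f"{path}: negative abundance at row {row_num}, column {col_num}"
                )
            parsed.append(value)
        rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no taxon rows")
    delimiter = _detect_delimiter(lineages)
    ranks = {lineage_rank(s, delimiter) for s in lineages}
    rank = ranks.pop() if len(ranks) == 1 else "mixed"
    return AbundanceTable(
        taxon_lineages=lineages,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        rank=rank,
        delimiter=delimiter,
    )


def write_profile_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table back out in the same tab-delimited dialect."""
    with open(path, "w") as fh:
        fh.write("Lineage\t" + "\t".join(table.sample_ids) + "\n")
        for lineage, row in zip(table.taxon_lineages, table.values):
            fh.write(lineage + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def collapse_to_rank(
    table: AbundanceTable, rank: str, drop_unclassified: bool = False
) -> AbundanceTable:
    """Collapse a (possibly multi-rank) table to a single taxonomic rank.

    Rows already at the requested rank are taken as-is; deeper rows whose
    rank-level prefix has no row of its own are truncated and summed (so a
    hierarchical table is not double-counted).  Rows terminating above the
    rank are aggregates of their descendants when descendant rows exist
    (skipped), and otherwise represent mass unclassified at this rank,
    pooled into an explicit "unclassified" bucket (or dropped).  Columns are
    renormalized to sum to 1 afterwards.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    delim = table.delimiter

    exact_keys = set()
    proper_prefixes = set()
    split = [_split_lineage(s, delim) for s in table.taxon_lineages]
    for parts in split:
        if len(parts) == depth:
            exact_keys.add(delim.join(parts))
        for j in range(1, len(parts)):
            proper_prefixes.add(delim.join(parts[:j]))

    if not any(len(parts) >= depth for parts in split):
        raise ValueError(f"no lineage in the table reaches rank {rank!r}")

    collapsed: dict[str, np.ndarray] = {}
    for parts, row in zip(split, table.values):
        if len(parts) < depth:
            if delim.join(parts) in proper_prefixes:
                continue  # cumulative parent of deeper rows, already counted
            key = UNCLASSIFIED
            if drop_unclassified:
                continue
        else:
            key = delim.join(parts[:depth])
            if len(parts) > depth and key in exact_keys:
                continue  # parent row already carries this mass
        collapsed[key] = collapsed.get(key, 0.0) + row

    lineages = sorted(collapsed)
    values = np.array([collapsed[k] for k in lineages], dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"samples with zero total abundance after collapse: {bad}")
    values = values / totals
    return AbundanceTable(
        taxon_lineages=lineages,
        sample_ids=list(table.sample_ids),
        values=values,
        rank=rank,
        delimiter=delim,
        sample_sites=dict(table.sample_sites) if table.sample_sites else None,
    )


def deduplicate_subjects(
    table: AbundanceTable, sample_to_subject: dict[str, str]
) -> tuple[AbundanceTable, int]:
    """Keep at most one sample per subject (first in stable column order).

    Returns the reduced table and the number of columns removed.
    """
    missing = [s for s in table.sample_ids if s not in sample_to_subject]
    if missing:
        raise ValueError(f"samples missing from subject mapping: {missing}")
    seen: set[str] = set()
    keep: list[int] = []
    for idx, sample in enumerate(table.sample_ids):
        subject = sample_to_subject[sample]
        if subject not in seen:
            seen.add(subject)
            keep.append(idx)
    removed = len(table.sample_ids) - len(keep)
    reduced = replace(
        table,
        sample_ids=[table.sample_ids[i] for i in keep],
        values=table.values[:, keep],
        sample_sites=(
            {table.sample_ids[i]: table.sample_sites[table.sample_ids[i]] for i in keep}
            if table.sample_sites
            else None
        ),
    )
    return reduced, removed


def site_diversity_summary(
    table: AbundanceTable,
    site: str,
    richness_mode: str = "observed",
    sample_sites: dict[str, str] | None = None,
) -> BodySiteSummary:
    """Alpha / gamma / beta summary for all samples of one body site.

    Beta is the mean (and sd, ddof=1) over all sample pairs of the
    Bray-Curtis dissimilarity; a single-sample site reports beta as NaN.
    """
    sites = sample_sites or table.sample_sites
    if sites is None:
        raise ValueError("no sample -> site mapping available")
    cols = [i for i, s in enumerate(table.sample_ids) if sites.get(s) == site]
    if not cols:
        raise ValueError(f"no samples for site {site!r}")
    mat = table.values[:, cols].T  # samples x taxa
    global_richness = mat.shape[1] if richness_mode == "global" else None
    a_mean, a_sd = alpha_diversity(mat, richness_mode, global_richness)
    gamma = gamma_diversity(mat, richness_mode, global_richness)
    if len(cols) > 1:
        pair_bc = pairwise_bray_curtis(mat)
        b_mean = float(pair_bc.mean())
        b_sd = float(pair_bc.std(ddof=1)) if pair_bc.size > 1 else 0.0
    else:
        b_mean = b_sd = float("nan")
    return BodySiteSummary(
        site=site,
        alpha_mean=a_mean,
        alpha_sd=a_sd,
        gamma=gamma,
        beta_mean=b_mean,
        beta_sd=b_sd,
        n_samples=len(cols),
    )


def summarize_sites(
    table: AbundanceTable,
    richness_mode: str = "observed",
    sample_sites: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One summary row per body site, in stable site order."""
    sites_map = sample_sites or table.sample_sites
    if sites_map is None:
        raise ValueError("no sample -> site mapping available")
    ordered_sites = list(dict.fromkeys(sites_map[s] for s in table.sample_ids))
    rows = [
        site_diversity_summary(table, site, richness_mode, sites_map)
        for site in ordered_sites
    ]
    return pd.DataFrame(
        {
            "site": [r.site for r in rows],
            "alpha_mean": [r.alpha_mean for r in rows],
            "alpha_sd": [r.alpha_sd for r in rows],
            "gamma": [r.gamma for r in rows],
            "beta_mean": [r.beta_mean for r in rows],
            "beta_sd": [r.beta_sd for r in rows],
            "n_samples": [r.n_samples for r in rows],
        }
    )


def generate_synthetic_profile(
    num_sites: int,
    genera_per_site: int,
    samples_per_site: int,
    concentration: float | np.ndarray = 0.5,
    seed: int = 0,
    replicates_per_subject: int = 1,
    site_names: list[str] | None = None,
) -> tuple[AbundanceTable, dict[str, str]]:
    """Synthetic HMP-dialect fixture with Dirichlet community structure.

    Each body site gets its own disjoint set of genera (nested under its own
    phylum); every sample of a site is an independent draw from a Dirichlet
    over those genera.  Rows are emitted at kingdom, phylum and genus rank so
    each rank's rows sum to 1 per sample, as in real community profiles.
    Returns the table (with ``sample_sites`` populated) and the
    sample -> subject mapping; consecutive ``replicates_per_subject`` samples
    of a site share a subject.
    """
    if min(num_sites, genera_per_site, samples_per_site) < 1:
        raise ValueError("all fixture dimensions must be >= 1")
    if replicates_per_subject < 1:
        raise ValueError("replicates_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentration, dtype=float)
    if conc.ndim == 0:
        conc = np.full(genera_per_site, float(conc))
    if conc.shape != (genera_per_site,) or (conc <= 0).any():
        raise ValueError("concentration must be a positive scalar or length-"
                         f"{genera_per_site} vector")
    if site_names is None:
        site_names = [f"site_{i:02d}" for i in range(num_sites)]
    if len(site_names) != num_sites:
        raise ValueError("site_names length must equal num_sites")

    total_samples = num_sites * samples_per_site
    sample_ids: list[str] = []
    sample_sites: dict[str, str] = {}
    sample_to_subject: dict[str, str] = {}
    for si, site in enumerate(site_names):
        for s in range(samples_per_site):
            sample = f"{site}.s{s:03d}"
            sample_ids.append(sample)
            sample_sites[sample] = site
            sample_to_subject[sample] = f"{site}.subj{s // replicates_per_subject:03d}"

    lineages: list[str] = ["k__Bacteria"]
    rows: list[np.ndarray] = [np.ones(total_samples)]
    genus_draws = [
        rng.dirichlet(conc, size=samples_per_site) for _ in range(num_sites)
    ]
    for si, site in enumerate(site_names):
        phylum = f"k__Bacteria|p__Phylum{si:02d}"
        phylum_row = np.zeros(total_samples)
        phylum_row[si * samples_per_site : (si + 1) * samples_per_site] = 1.0
        lineages.append(phylum)
        rows.append(phylum_row)
        for g in range(genera_per_site):
            lineage = (
                f"{phylum}|c__Class{si:02d}|o__Order{si:02d}"
                f"|f__Family{si:02d}|g__Genus{si:02d}x{g:03d}"
            )
            row = np.zeros(total_samples)
            row[si * samples_per_site : (si + 1) * samples_per_site] = genus_draws[
                si
            ][:, g]
            lineages.append(lineage)
            rows.append(row)

    table = AbundanceTable(
        taxon_lineages=lineages,
        sample_ids=sample_ids,
        values=np.array(rows),
        rank="mixed",
        delimiter="|",
        sample_sites=sample_sites,
    )
    return table, sample_to_subject
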