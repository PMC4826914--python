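"""One-to-one ortholog identification by best reciprocal hits (BRH).

Two genes in different species are called orthologs when each is the
other's best similarity hit and both hits pass the E-value gate
(E < 1e-10 by default, applied in both search directions).  Best hits are
the smallest E-value, ties broken by larger bit score; a residual tie is
treated as ambiguous and yields no hit.  Complete ortholog groups contain
exactly one gene per species; by default groups missing any species are
dropped.

Hit tables use the BLAST tabular (outfmt 6) dialect.  For synthetic runs
without an external aligner, `kmer_similarity_scores` provides a built-in
scorer: the score is the number of shared k-mers and the pseudo-E-value is
the monotone transform 10**(-score) (not a statistical E-value; it exists
only so the same gating machinery applies).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EVALUE_CUTOFF = 1e-10

HIT_COLUMNS = ["query", "subject", "evalue", "bitscore"]


@dataclass
class OrthologGroup:
    """A focal gene and its per-species orthologs."""

    focal: str
    members: dict[str, str] = field(default_factory=dict)  # species -> gene id
    complete: bool = True


def read_blast_tabular(path) -> pd.DataFrame:
    """Read an outfmt-6-like file, keeping query, subject, E-value, bit score.

    Accepts either the full 12-column format or a minimal 4-column one.
    Duplicate (query, subject) rows keep the best record (smallest E-value,
    then largest bit score).
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    ncols = first.shape[1]
    if ncols >= 12:
        use, names = [0, 1, 10, 11], HIT_COLUMNS
    elif ncols == 4:
        use, names = [0, 1, 2, 3], HIT_COLUMNS
    else:
        raise ValueError(f"unrecognized hit-table layout with {ncols} columns")
    df = pd.read_csv(path, sep="\t", header=None, usecols=use)
    df.columns = names
    return dedupe_hits(df)


def dedupe_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (query, subject): best E-value, then best bit score."""
    ev = hits["evalue"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ev)) or (ev < 0).any():
        raise ValueError("E-values must be finite and >= 0")
    if (hits["bitscore"] <= 0).any():
        raise ValueError("bit scores must be > 0")
    out = hits.sort_values(
        ["query", "subject", "evalue", "bitscore"], ascending=[True, True, True, False]
    ).drop_duplicates(["query", "subject"], keep="first")
    return out.reset_index(drop=True)


def best_hit(hits: pd.DataFrame, query: str, cutoff: float = DEFAULT_EVALUE_CUTOFF) -> str | None:
    """Best subject for one query, or None (no passing hit, or an unresolved tie)."""
    sub = hits[(hits["query"] == query) & (hits["evalue"] < cutoff)]
    if sub.empty:
        return None
    best_e = sub["evalue"].min()
    at_e = sub[sub["evalue"] == best_e]
    best_b = at_e["bitscore"].max()
    winners = at_e[at_e["bitscore"] == best_b]
    if len(winners) > 1:
        return None  # ambiguous best hit: conservative, deterministic
    return str(winners["subject"].iloc[0])


def _best_hits_all(hits: pd.DataFrame, cutoff: float) -> dict[str, str]:
    """Vectorized best_hit for every query in the table (same tie rules)."""
    sub = hits[hits["evalue"] < cutoff]
    if sub.empty:
        return {}
    sub = sub.sort_values(["query", "evalue", "bitscore"], ascending=[True, True, False])
    top = sub.groupby("query", sort=False).first()
    # detect residual ties: another row with identical (evalue, bitscore)
    merged = sub.merge(
        top.reset_index()[["query", "evalue", "bitscore"]],
        on=["query", "evalue", "bitscore"],
        how="inner",
    )
    tie_counts = merged.groupby("query").size()
    return {
        q: str(top.loc[q, "subject"])
        for q in top.index
        if tie_counts.get(q, 1) == 1
    }


def best_reciprocal_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[tuple[str, str]]:
    """(a, b) pairs where a's best hit is b, b's best hit is a, both passing.

    Gene-id namespaces of the two species must not overlap.
    """
    ids_a = set(hits_ab["query"]) | set(hits_ba["subject"])
    ids_b = set(hits_ab["subject"]) | set(hits_ba["query"])
    overlap = ids_a & ids_b
    if overlap:
        raise ValueError(f"gene-id namespaces overlap across species: {sorted(overlap)[:5]}")
    fwd = _best_hits_all(hits_ab, cutoff)
    rev = _best_hits_all(hits_ba, cutoff)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


def build_groups(
    focal_species: str,
    pairings_per_species: dict[str, list[tuple[str, str]]],
    require_all: bool = True,
) -> list[OrthologGroup]:
    """Assemble per-focal-gene ortholog groups from focal-vs-other BRH pairs.

    `pairings_per_species` maps each non-focal species to its (focal gene,
    ortholog) BRH list.  With require_all, groups missing any species are
    dropped; otherwise they are kept and flagged incomplete.
    """
    per_focal: dict[str, dict[str, str]] = defaultdict(dict)
    for species, pairs in pairings_per_species.items():
        if species == focal_species:
            raise ValueError("pairings must be focal-vs-other species")
        for focal, other in pairs:
            if species in per_focal[focal]:
                raise ValueError(
                    f"focal gene {focal} paired to two genes in species {species}"
                )
            per_focal[focal][species] = other
    n_species = len(pairings_per_species)
    groups = []
    for focal in sorted(per_focal):
        members = per_focal[focal]
        complete = len(members) == n_species
        if require_all and not complete:
            continue
        groups.append(OrthologGroup(focal=focal, members=dict(members), complete=complete))
    return groups


def longest_isoform(proteome: dict[str, list[str]]) -> dict[str, str]:
    """Keep the longest protein per gene; length ties resolved lexicographically."""
    return {
        gene: max(seqs, key=lambda s: (len(s), s))
        for gene, seqs in proteome.items()
        if seqs
    }


def kmer_similarity_scores(
    proteome_a: dict[str, str], proteome_b: dict[str, str], k: int = 5
) -> pd.DataFrame:
    """Shared-k-mer hit table between two proteomes (built-in scorer).

    score = number of distinct shared k-mers; pseudo-E-value = 10**(-score)
    capped at 1.  The transform is monotone only — it is not a statistical
    E-value — so the standard E-value gate can be reused on synthetic data.
    Pairs sharing no k-mer are omitted.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    for name, prot in (("first", proteome_a), ("second", proteome_b)):
        if any(len(s) == 0 for s in prot.values()):
            raise ValueError(f"empty sequence in {name} proteome")
    index: dict[str, list[str]] = defaultdict(list)
    kmers_b = {
        gene: {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for gene, seq in proteome_b.items()
    }
    for gene, ks in kmers_b.items():
        for km in ks:
            index[km].append(gene)
    rows = []
    for ga, seq in proteome_a.items():
        counts: dict[str, int] = defaultdict(int)
        for km in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            for gb in index.get(km, ()):
                counts[gb] += 1
        for gb, score in counts.items():
            rows.append((ga, gb, min(10.0 ** (-score), 1.0), float(score)))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def groups_to_frame(groups: list[OrthologGroup], species_order: list[str]) -> pd.DataFrame:
    """TSV-ready table: focal id plus one column per species."""
    rows = []
    for g in groups:
        row = {"focal": g.focal, "complete": g.complete}
        for sp in species_order:
            row[sp] = g.members.get(sp, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=["focal", "complete", *species_order])
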