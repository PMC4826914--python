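"""Alignment quality control: block filtering, singleton-window masks, back-translation.

Automatically annotated genomes contain imperfect gene models, and site
tests of positive selection are notoriously sensitive to the resulting
alignment errors: a mis-annotated segment in one sequence shows up as a
run of "singleton" residues (present in exactly one sequence) that the
likelihood can only explain with a high-omega class.  The guard is a
filtering cascade on the protein alignment:

1. `filter_blocks` — a Gblocks-style conserved-block filter: gap-containing
   or low-majority columns are nonconserved; long nonconserved runs and
   short surviving blocks are masked.  (Approximate; a real Gblocks result
   can be supplied as a pre-masked alignment instead.)
2. `singleton_window_mask` — the sliding-window singleton rules, applied
   exactly: every 15-column window in which a single sequence carries >= 10
   singleton residues, and every 5-column window in which a single
   sequence is singleton at all 5 positions, are masked entirely.
3. `backtranslate` — maps retained protein columns onto codons from the
   raw CDSs to produce the codon alignment the selection test consumes.

Masks carry per-rule provenance (1-based protein columns); removal is
always the union.  Windows are evaluated at every start offset, and the
manual-editing step of the original protocol is replaced by re-testing
after applying an externally supplied extra mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import translate_cds
from .msa import Alignment

GAP = "-"

RULES = ("block", "window15", "window5", "extra")


@dataclass
class MaskAnnotation:
    """Per-rule sets of 1-based alignment columns slated for removal."""

    columns: dict[str, set[int]] = field(default_factory=dict)

    def add(self, rule: str, cols) -> None:
        if rule not in RULES:
            raise ValueError(f"unknown mask rule {rule!r}")
        self.columns.setdefault(rule, set()).update(int(c) for c in cols)

    def union(self) -> set[int]:
        out: set[int] = set()
        for cols in self.columns.values():
            out |= cols
        return out

    def merged(self, other: "MaskAnnotation") -> "MaskAnnotation":
        out = MaskAnnotation()
        for m in (self, other):
            for rule, cols in m.columns.items():
                out.add(rule, cols)
        return out

    def validate(self, n_columns: int) -> None:
        for rule, cols in self.columns.items():
            bad = [c for c in cols if not 1 <= c <= n_columns]
            if bad:
                raise ValueError(f"mask rule {rule} has out-of-range columns {bad[:5]}")

    def to_frame(self, gene: str) -> pd.DataFrame:
        rows = [
            (gene, rule, col)
            for rule in sorted(self.columns)
            for col in sorted(self.columns[rule])
        ]
        return pd.DataFrame(rows, columns=["gene", "rule", "column"])


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(s) for s in alignment.seqs])


def filter_blocks(
    alignment: Alignment,
    min_conserved_frac: float = 0.5,
    max_nonconserved_run: int = 8,
    min_block_len: int = 10,
) -> MaskAnnotation:
    """Conserved-block filter over the protein alignment.

    A column is conserved iff it is gap-free and its modal residue
    frequency exceeds min_conserved_frac.  Runs of more than
    max_nonconserved_run consecutive nonconserved columns are masked; the
    surviving stretches between masked regions are then masked too when
    shorter than min_block_len.
    """
    mat = _char_matrix(alignment)
    n_rows, n_cols = mat.shape
    # modal residue count per column = max over rows of "rows equal to me"
    eq_count = (mat[:, None, :] == mat[None, :, :]).sum(axis=1)
    gap_free = ~(mat == GAP).any(axis=0)
    conserved = gap_free & (eq_count.max(axis=0) / n_rows > min_conserved_frac)

    masked = np.zeros(n_cols, dtype=bool)
    # long nonconserved runs
    run_start = None
    for c in range(n_cols + 1):
        if c < n_cols and not conserved[c]:
            if run_start is None:
                run_start = c
        else:
            if run_start is not None and c - run_start > max_nonconserved_run:
                masked[run_start:c] = True
            run_start = None
    # short surviving blocks
    seg_start = None
    for c in range(n_cols + 1):
        if c < n_cols and not masked[c]:
            if seg_start is None:
                seg_start = c
        else:
            if seg_start is not None and c - seg_start < min_block_len:
                masked[seg_start:c] = True
            seg_start = None

    mask = MaskAnnotation()
    mask.add("block", (np.nonzero(masked)[0] + 1).tolist())
    return mask


def singleton_matrix(alignment: Alignment) -> np.ndarray:
    """Boolean (rows, columns): True where the residue is a singleton.

    A singleton is a non-gap residue carried by exactly one sequence at
    that column and different from every other sequence's residue; gaps
    never count, on either side of the comparison.
    """
    mat = _char_matrix(alignment)
    eq_count = (mat[:, None, :] == mat[None, :, :]).sum(axis=1)
    return (eq_count == 1) & (mat != GAP)


def singleton_window_mask(
    alignment: Alignment,
    long_window: int = 15,
    long_threshold: int = 10,
    short_window: int = 5,
) -> MaskAnnotation:
    """Sliding-window singleton rules (stride 1, windows masked in full).

    Masks the union of every `long_window`-column window in which some
    single sequence has >= `long_threshold` singleton positions, plus
    every `short_window`-column window in which some single sequence is a
    singleton at all positions.  Alignments shorter than the short window
    yield an empty mask.
    """
    if alignment.n_rows < 3:
        raise ValueError("singleton masking needs at least 3 sequences")
    s = singleton_matrix(alignment)
    n_cols = s.shape[1]
    mask = MaskAnnotation()
    mask.columns.setdefault("window15", set())
    mask.columns.setdefault("window5", set())
    for window, rule, needed in (
        (long_window, "window15", long_threshold),
        (short_window, "window5", short_window),
    ):
        if n_cols < window:
            continue
        # per-taxon rolling singleton counts over each window
        csum = np.cumsum(np.pad(s, ((0, 0), (1, 0))), axis=1, dtype=int)
        counts = csum[:, window:] - csum[:, :-window]  # (rows, n_windows)
        hit_windows = np.nonzero((counts >= needed).any(axis=0))[0]
        for w0 in hit_windows:
            mask.columns[rule].update(range(w0 + 1, w0 + window + 1))
    return mask


def backtranslate(
    protein_alignment: Alignment,
    cds_map: dict[str, str],
    mask: MaskAnnotation | None = None,
) -> Alignment:
    """Build the codon alignment from the protein alignment, CDSs and mask.

    Each retained protein column maps to the corresponding codon of that
    taxon's CDS (protein gaps map to the gap codon '---'); masked columns
    are dropped.  Each ungapped protein row must equal the translation of
    its CDS (a trailing stop codon on the CDS is tolerated and trimmed).
    """
    removed = mask.union() if mask is not None else set()
    if mask is not None:
        mask.validate(protein_alignment.length)
    keep = [c for c in range(protein_alignment.length) if c + 1 not in removed]
    out_seqs = []
    for taxon, row in zip(protein_alignment.ids, protein_alignment.seqs):
        cds = cds_map[taxon].upper()
        if len(cds) % 3:
            raise ValueError(f"{taxon}: CDS length not divisible by 3")
        ungapped = row.replace(GAP, "")
        translated = translate_cds(cds)
        if translated.endswith("*"):
            translated = translated[:-1]
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{taxon}: CDS length {len(cds)} != 3 x ungapped protein length {len(ungapped)}"
            )
        for i, (aa_obs, aa_cds) in enumerate(zip(ungapped, translated)):
            if aa_obs != aa_cds:
                raise ValueError(
                    f"{taxon}: translation mismatch at protein position {i + 1} "
                    f"({aa_obs!r} in alignment vs {aa_cds!r} from CDS)"
                )
        pieces = []
        pos = 0
        for c in range(protein_alignment.length):
            if row[c] == GAP:
                pieces.append("---")
            else:
                pieces.append(cds[3 * pos : 3 * pos + 3])
                pos += 1
        out_seqs.append("".join(pieces[c] for c in keep))
    return Alignment(ids=list(protein_alignment.ids), seqs=out_seqs)


def write_mask_tsv(masks: dict[str, MaskAnnotation], path) -> None:
    frames = [m.to_frame(g) for g, m in sorted(masks.items())]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_mask_tsv(path) -> dict[str, MaskAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, MaskAnnotation] = {}
    for gene, sub in df.groupby("gene"):
        m = MaskAnnotation()
        for rule, cols in sub.groupby("rule"):
            m.add(str(rule), cols["column"].tolist())
        out[str(gene)] = m
    return out
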