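"""Prokaryotic HD-domain dNTPase family census and conservation analysis.

The HD-domain dNTP triphosphohydrolases of prokaryotes split into two
divergent families: SAMHD1-like enzymes (two-lobed, with the C-lobe that
mediates tetramerization/allostery in SAMHD1) and Dgt-like enzymes (named
after the E. coli deoxyguanosine triphosphate triphosphohydrolase, lacking
the C-lobe).  This module assigns protein sequences to one family or the
other by scoring against position-specific log-odds profiles with
extreme-value-calibrated E-values, using the decision rule that a sequence
belongs to a family only if its E-value against that family's profile is
better by a log10 margin (default 18 decades); tabulates a census over
taxonomy restricted to circular chromosomes longer than 200 kb; thins
alignments to one representative per 70 %-identity group; computes sequence
logos; and annotates logo columns by proximity (<= 5 Angstrom) of the
corresponding structural residues to active-site or allosteric ligands.

Sequence metadata travel on pipe-delimited FASTA definition lines::

    >PROTEIN_ACC|NUCLEOTIDE_ACC|Domain;Phylum;Class;...

Pairwise global alignments (identity, structure-to-alignment mapping) use
Bio.Align.PairwiseAligner; the profile local alignment is implemented here
because it scores a sequence against a position-specific matrix.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "AnnotatedSequence",
    "ChromosomeRecord",
    "FamilyProfile",
    "ClassificationResult",
    "LogoMatrix",
    "parse_defline",
    "format_defline",
    "read_fasta",
    "write_fasta",
    "read_chromosome_table",
    "build_profile",
    "fit_gumbel",
    "calibrate_evalue",
    "score_profile_local",
    "score_and_classify",
    "flag_truncated",
    "census_counts",
    "pairwise_identity",
    "thin_by_identity",
    "compute_logo",
    "annotate_proximity",
    "map_structure_to_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = "-."

#: default affine gap penalties (bits) for profile local alignment
GAP_OPEN = 4.0
GAP_EXTEND = 0.25

#: classification margin: "preferred one or the other model by a factor of
#: at least 10^18 in E value"
DEFAULT_MARGIN_LOG10 = 18.0

#: chromosome census filter: circular and > 200 kb
MIN_CHROMOSOME_BP = 200_000


# ---------------------------------------------------------------------------
# records and deflines


@dataclass
class AnnotatedSequence:
    """Protein sequence with genome/taxonomy metadata."""

    protein_acc: str
    nucleotide_acc: str
    taxonomy: list
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).upper()
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"{self.protein_acc}: invalid residue(s) {sorted(bad)}"
            )
        if not self.taxonomy:
            raise ValueError(f"{self.protein_acc}: taxonomy must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChromosomeRecord:
    nucleotide_acc: str
    length_bp: int
    topology: str  # "circular" | "linear"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")

    @property
    def passes_census_filter(self) -> bool:
        return self.topology == "circular" and self.length_bp > MIN_CHROMOSOME_BP


class DeflineError(ValueError):
    pass


def parse_defline(header: str, strict: bool = True):
    """Split ``acc|nuc_acc|Tax;onomy`` into its three fields.

    In permissive mode a missing nucleotide accession or taxonomy becomes
    an empty field instead of an error.
    """
    parts = header.strip().lstrip(">").split("|")
    if strict and (len(parts) != 3 or any(not p for p in parts)):
        raise DeflineError(
            f"defline {header!r} does not match 'protein|nucleotide|taxonomy'"
        )
    protein_acc = parts[0] if parts else ""
    nucleotide_acc = parts[1] if len(parts) > 1 else ""
    taxonomy = [t for t in (parts[2].split(";") if len(parts) > 2 else []) if t]
    if strict and not taxonomy:
        raise DeflineError(f"defline {header!r} has empty taxonomy")
    return protein_acc, nucleotide_acc, taxonomy


def format_defline(seq: AnnotatedSequence) -> str:
    return f"{seq.protein_acc}|{seq.nucleotide_acc}|{';'.join(seq.taxonomy)}"


def read_fasta(path, strict: bool = True) -> list[AnnotatedSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        acc, nuc, tax = parse_defline(header, strict=strict)
        out.append(
            AnnotatedSequence(
                protein_acc=acc,
                nucleotide_acc=nuc,
                taxonomy=tax or ["Unknown"],
                sequence=str(rec.seq),
            )
        )
    return out


def write_fasta(sequences: Iterable[AnnotatedSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=format_defline(s), description="")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chromosome_table(path) -> list[ChromosomeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChromosomeRecord(str(r.nucleotide_acc), int(r.length_bp), str(r.topology))
        for r in df.itertuples()
    ]


def write_chromosome_table(chromosomes: Iterable[ChromosomeRecord], path) -> None:
    pd.DataFrame(
        [
            {"nucleotide_acc": c.nucleotide_acc, "length_bp": c.length_bp, "topology": c.topology}
            for c in chromosomes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# family profiles


@dataclass
class FamilyProfile:
    """Position-specific log-odds model of one dNTPase family.

    ``log_odds`` has shape (n_columns, 20), in bits, against ``background``.
    ``gumbel_lambda``/``gumbel_k`` parameterize the E-value of a local
    alignment score S as  E(S) = k * exp(-lambda * S).
    """

    name: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    excluded_columns: list = field(default_factory=list)
    gumbel_lambda: float | None = None
    gumbel_k: float | None = None

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_lambda is not None

    def log10_evalue(self, score: float) -> float:
        if not self.calibrated:
            raise ValueError(f"profile {self.name!r} is not E-value calibrated")
        return (math.log(self.gumbel_k) - self.gumbel_lambda * score) / math.log(10.0)


def build_profile(
    seed_alignment: Sequence[str],
    name: str = "family",
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> FamilyProfile:
    """Per-column log-odds profile from an aligned set of sequences.

    Frequencies use an additive pseudocount over the 20 amino acids;
    columns with more than ``max_gap_fraction`` gaps are excluded (their
    original indices are reported in ``excluded_columns``).  X residues are
    ignored in the counts.
    """
    if len(seed_alignment) == 0:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    ncol = lengths.pop()
    if ncol == 0:
        raise ValueError("alignment has zero columns")
    bg = (
        np.full(20, 0.05)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")

    rows = [s.upper() for s in seed_alignment]
    kept, excluded = [], []
    for j in range(ncol):
        col = [r[j] for r in rows]
        gaps = sum(c in GAP_CHARS for c in col)
        if gaps / len(col) > max_gap_fraction:
            excluded.append(j)
            continue
        counts = np.zeros(20)
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        freqs = (counts + pseudocount) / (counts.sum() + 20.0 * pseudocount)
        kept.append(np.log2(freqs / bg))
    if not kept:
        raise ValueError("all columns are gap-majority; nothing to model")
    return FamilyProfile(
        name=name,
        log_odds=np.array(kept),
        background=bg,
        pseudocount=pseudocount,
        excluded_columns=excluded,
    )


# ---------------------------------------------------------------------------
# profile local alignment (Smith–Waterman, affine gaps, vectorized rows)


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in seq.upper()], dtype=int)


def _sw_forward(
    log_odds: np.ndarray,
    enc: np.ndarray,
    gap_open: float,
    gap_extend: float,
):
    """Best local score and its end cell (profile row, sequence column).

    Row-vectorized affine-gap Smith–Waterman.  Within a row, the
    gap-in-profile state is resolved with a prefix-max transform, which is
    exact for gap_open >= gap_extend (re-entering a gap from inside another
    gap is never optimal).
    """
    L, n = log_odds.shape[0], enc.shape[0]
    # substitution score of every sequence position against each column;
    # X/unknown residues score 0
    sub = np.zeros((L, n))
    valid = enc >= 0
    sub[:, valid] = log_odds[:, enc[valid]]

    neg = -1e30
    h_prev = np.zeros(n + 1)
    ix_prev = np.full(n + 1, neg)
    best, best_i, best_j = 0.0, 0, 0
    idx = np.arange(n + 1)
    for i in range(L):
        m = h_prev[:-1] + sub[i]  # diagonal (match) into column j+1
        ix = np.maximum(h_prev - gap_open, ix_prev - gap_extend)  # gap in seq
        base = np.zeros(n + 1)
        base[1:] = np.maximum(m, ix[1:])
        base = np.maximum(base, 0.0)
        # gap-in-profile (consume sequence): prefix-max transform; a gap of
        # length l starting after base[k] costs gap_open + (l-1)*gap_extend
        t = base - gap_open + gap_extend * idx
        run = np.maximum.accumulate(t)
        iy = np.full(n + 1, neg)
        iy[1:] = run[:-1] - gap_extend * (idx[1:] - 1)
        h = np.maximum(base, iy)
        jmax = int(np.argmax(h))
        if h[jmax] > best:
            best, best_i, best_j = float(h[jmax]), i, jmax - 1
        h_prev, ix_prev = h, ix
    return best, best_i, best_j


def score_profile_local(
    profile: FamilyProfile,
    sequence: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
):
    """Best local profile-to-sequence alignment score (bits) and extent.

    Returns ``(score, (col_start, col_end), (seq_start, seq_end))`` with
    inclusive 0-based bounds of the optimal local path.  The path start is
    located by rerunning the forward pass on the reversed problem.
    """
    enc = _encode(sequence)
    if enc.size == 0:
        raise ValueError("empty sequence")
    score, i_end, j_end = _sw_forward(profile.log_odds, enc, gap_open, gap_extend)
    if score <= 0:
        return 0.0, (0, -1), (0, -1)
    sub_rev = profile.log_odds[i_end::-1]
    enc_rev = enc[j_end::-1]
    score_r, i_r, j_r = _sw_forward(sub_rev, enc_rev, gap_open, gap_extend)
    i_start = i_end - i_r
    j_start = j_end - j_r
    return score, (i_start, i_end), (j_start, j_end)


# ---------------------------------------------------------------------------
# E-value calibration


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Fit a Gumbel (EVD) to a sample of best local scores.

    Returns (lambda, mu) of the distribution with survival function
    approx exp(-lambda (s - mu)) in its right tail.
    """
    from scipy.stats import gumbel_r

    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise ValueError("degenerate (zero-variance) score distribution")
    mu, beta = gumbel_r.fit(scores)
    return 1.0 / beta, mu


def calibrate_evalue(
    profile: FamilyProfile,
    n_shuffles: int = 200,
    seed: int = 0,
    shuffle_length: int | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> FamilyProfile:
    """Calibrate the profile's E-value parameters on random sequences.

    ``n_shuffles`` random sequences drawn from the profile background
    (length ``shuffle_length``, default 1.5x profile length) are scored;
    their best local scores are fitted to an extreme-value distribution.
    With lambda and mu from the fit, E(S) = k exp(-lambda S) where
    k = exp(lambda mu), so that E(mu) = 1 — the expected number of
    random sequences reaching the modal best score is order one.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable calibration")
    rng = np.random.default_rng(seed)
    length = shuffle_length or max(int(1.5 * profile.length), 50)
    aas = np.array(list(AMINO_ACIDS))
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        seq = "".join(rng.choice(aas, size=length, p=profile.background))
        scores[i], _, _ = score_profile_local(profile, seq, gap_open, gap_extend)
    lam, mu = fit_gumbel(scores)
    profile.gumbel_lambda = lam
    profile.gumbel_k = math.exp(lam * mu)
    return profile


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationResult:
    protein_acc: str
    score_a: float
    score_b: float
    log10_e_a: float
    log10_e_b: float
    margin: float
    label: str  # family_a | family_b | ambiguous
    coverage: float
    truncated_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "protein_acc": self.protein_acc,
            "score_a": self.score_a,
            "score_b": self.score_b,
            "log10_e_a": self.log10_e_a,
            "log10_e_b": self.log10_e_b,
            "margin": self.margin,
            "label": self.label,
            "coverage": self.coverage,
            "truncated_flag": self.truncated_flag,
        }


def score_and_classify(
    seq: AnnotatedSequence,
    profile_a: FamilyProfile,
    profile_b: FamilyProfile,
    margin_threshold_log10: float = DEFAULT_MARGIN_LOG10,
) -> ClassificationResult:
    """Assign a sequence to one of two families by E-value margin.

    The sequence is locally aligned against both calibrated profiles; the
    label goes to the family with the lower log10 E-value provided the
    margin is at least ``margin_threshold_log10`` decades, else
    ``ambiguous``.  ``coverage`` is the aligned fraction of the winning
    (or, for ambiguous calls, better-scoring) profile's columns.
    """
    if not (profile_a.calibrated and profile_b.calibrated):
        raise ValueError("both profiles must be E-value calibrated")
    if seq.length < 20:
        raise ValueError(f"{seq.protein_acc}: sequence shorter than 20 residues")
    score_a, cols_a, _ = score_profile_local(profile_a, seq.sequence)
    score_b, cols_b, _ = score_profile_local(profile_b, seq.sequence)
    e_a = profile_a.log10_evalue(score_a)
    e_b = profile_b.log10_evalue(score_b)
    margin = abs(e_a - e_b)
    if margin < margin_threshold_log10:
        label = "ambiguous"
    else:
        label = "family_a" if e_a < e_b else "family_b"
    if e_a <= e_b:
        cov_cols, cov_len = cols_a, profile_a.length
    else:
        cov_cols, cov_len = cols_b, profile_b.length
    coverage = max(cov_cols[1] - cov_cols[0] + 1, 0) / cov_len
    return ClassificationResult(
        protein_acc=seq.protein_acc,
        score_a=score_a,
        score_b=score_b,
        log10_e_a=e_a,
        log10_e_b=e_b,
        margin=margin,
        label=label,
        coverage=coverage,
    )


def flag_truncated(
    result: ClassificationResult, min_coverage: float = 0.7
) -> bool:
    """True iff the aligned profile coverage falls below ``min_coverage``.

    Truncated members (gene disruptions, misannotated starts) are excluded
    from alignments and logos but retained in the census.  The boundary is
    a strict less-than: coverage exactly at the threshold is full length.
    """
    flag = result.coverage < min_coverage
    result.truncated_flag = flag
    return flag


# ---------------------------------------------------------------------------
# census


def census_counts(
    results: Sequence[ClassificationResult],
    sequences: Sequence[AnnotatedSequence],
    chromosomes: Sequence[ChromosomeRecord],
    level: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon family counts over filtered chromosomes.

    Only circular chromosomes of more than 200,000 bp enter the census;
    proteins on excluded chromosomes are dropped from the counts entirely.
    ``level`` is the 1-based taxonomy depth (1 = domain).  Returns
    ``(census, copy_numbers)``: the census has one row per taxon with
    n_family_a, n_family_b and n_chromosomes; the side table reports how
    many chromosomes carry 0, 1, 2 or 3+ classified dNTPases.
    """
    if level < 1:
        raise ValueError("level must be >= 1 (1 = domain)")
    seq_by_acc = {s.protein_acc: s for s in sequences}
    chrom_by_acc = {c.nucleotide_acc: c for c in chromosomes}
    max_depth = max((len(s.taxonomy) for s in sequences), default=0)
    if sequences and level > max_depth:
        raise ValueError(
            f"taxonomy level {level} exceeds available depth {max_depth}"
        )

    kept_chroms = [c for c in chromosomes if c.passes_census_filter]
    kept_accs = {c.nucleotide_acc for c in kept_chroms}

    rows = []
    per_chrom = {acc: 0 for acc in kept_accs}
    for res in results:
        seq = seq_by_acc.get(res.protein_acc)
        if seq is None:
            continue
        chrom = chrom_by_acc.get(seq.nucleotide_acc)
        if chrom is None:
            warnings.warn(
                f"{res.protein_acc}: nucleotide accession "
                f"{seq.nucleotide_acc!r} not in the chromosome table; "
                "counted under 'unplaced'"
            )
            taxon = "unplaced"
        elif seq.nucleotide_acc not in kept_accs:
            continue  # chromosome fails the circular/>200 kb filter
        else:
            taxon = seq.taxonomy[min(level, len(seq.taxonomy)) - 1]
            per_chrom[seq.nucleotide_acc] += 1
        rows.append({"taxon": taxon, "label": res.label})

    # chromosome counts per taxon need sequence-independent taxonomy; use the
    # taxonomy of any sequence on that chromosome when available
    chrom_taxon = {}
    for s in sequences:
        if s.nucleotide_acc in kept_accs and s.nucleotide_acc not in chrom_taxon:
            chrom_taxon[s.nucleotide_acc] = s.taxonomy[min(level, len(s.taxonomy)) - 1]

    taxa = sorted(
        {r["taxon"] for r in rows} | set(chrom_taxon.values())
    )
    census_rows = []
    for taxon in taxa:
        sub = [r for r in rows if r["taxon"] == taxon]
        census_rows.append(
            {
                "taxon": taxon,
                "n_family_a": sum(r["label"] == "family_a" for r in sub),
                "n_family_b": sum(r["label"] == "family_b" for r in sub),
                "n_ambiguous": sum(r["label"] == "ambiguous" for r in sub),
                "n_chromosomes": sum(
                    t == taxon for t in chrom_taxon.values()
                ),
            }
        )
    census = pd.DataFrame(
        census_rows,
        columns=["taxon", "n_family_a", "n_family_b", "n_ambiguous", "n_chromosomes"],
    )

    copies = pd.Series(
        [min(v, 3) for v in per_chrom.values()], dtype=int
    ).value_counts()
    copy_numbers = pd.DataFrame(
        {
            "copies": ["0", "1", "2", "3+"],
            "n_chromosomes": [int(copies.get(i, 0)) for i in range(4)],
        }
    )
    return census, copy_numbers


# ---------------------------------------------------------------------------
# identity thinning


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # end gaps free: truncated sequences align to their covered segment
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.86 naming
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, normalized by the shorter sequence.

    Match +1 / mismatch 0 with affine gaps and free end gaps; identity is
    the number of identical aligned positions divided by the length of the
    shorter sequence.  Symmetric and in [0, 1].
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _identity_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    ta, qa = aln[0], aln[1]
    matches = sum(
        1 for x, y in zip(ta, qa) if x == y and x not in GAP_CHARS
    )
    return min(matches / min(len(a), len(b)), 1.0)


def thin_by_identity(
    sequences: Sequence[AnnotatedSequence], threshold: float = 0.70
) -> tuple[list[AnnotatedSequence], dict]:
    """Greedy representative selection at an identity threshold.

    Sequences are visited in order of descending length (ties broken by
    ascending protein accession); each becomes a new representative unless
    it is at least ``threshold`` identical to an existing representative,
    in which case it is assigned to the first such representative in
    creation order.  Deterministic.  Returns (representatives,
    {protein_acc: representative_acc}).
    """
    if not sequences:
        raise ValueError("no sequences to thin")
    ordered = sorted(sequences, key=lambda s: (-s.length, s.protein_acc))
    reps: list[AnnotatedSequence] = []
    assignment: dict[str, str] = {}
    for seq in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(seq.sequence, rep.sequence) >= threshold:
                home = rep
                break
        if home is None:
            reps.append(seq)
            assignment[seq.protein_acc] = seq.protein_acc
        else:
            assignment[seq.protein_acc] = home.protein_acc
    return reps, assignment


# ---------------------------------------------------------------------------
# sequence logos


@dataclass
class LogoMatrix:
    """Per-column conservation of a multiple-sequence alignment.

    ``information`` is the column information content in bits
    (log2 20 minus the residue-frequency Shannon entropy, gaps excluded,
    optionally small-sample corrected); ``heights`` (n_columns x 20) are the
    letter heights, frequency * IC * occupancy, so they sum per column to
    IC * occupancy; ``site_category`` labels columns as active / allosteric
    / none from structure-proximity annotation.
    """

    information: np.ndarray
    heights: np.ndarray
    occupancy: np.ndarray
    site_category: list

    @property
    def n_columns(self) -> int:
        return self.information.shape[0]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "alphabet": AMINO_ACIDS,
                "information": self.information.tolist(),
                "heights": self.heights.tolist(),
                "occupancy": self.occupancy.tolist(),
                "site_category": self.site_category,
            },
            **kwargs,
        )

    def plot(self, ax=None):
        """Simple stacked-bar rendering (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, self.n_columns / 5), 2.5))
        colors = {"active": "green", "allosteric": "red", "none": "0.6"}
        bottom = np.zeros(self.n_columns)
        order = np.argsort(-self.heights, axis=1)
        xs = np.arange(1, self.n_columns + 1)
        for rank in range(min(4, 20)):
            h = np.take_along_axis(self.heights, order[:, rank : rank + 1], 1)[:, 0]
            ax.bar(
                xs,
                h,
                bottom=bottom,
                color=[colors.get(c, "0.6") for c in self.site_category],
                edgecolor="none",
                alpha=1.0 - 0.18 * rank,
            )
            bottom += h
        ax.set_xlabel("alignment column")
        ax.set_ylabel("bits")
        return ax


def compute_logo(
    alignment: Sequence[str],
    corrections: str = "none",
    site_category: Sequence[str] | None = None,
) -> LogoMatrix:
    """Information-content logo of an alignment.

    Gaps are excluded from the frequencies; each column's information is
    scaled by occupancy (the non-gap fraction) in the letter heights, so
    poorly populated columns cannot dominate the logo.
    ``corrections='small_sample'`` subtracts the standard small-sample bias
    term (19 / (2 ln 2 n)), floored at zero.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    if corrections not in ("none", "small_sample"):
        raise ValueError("corrections must be 'none' or 'small_sample'")
    lengths = {len(r) for r in alignment}
    if len(lengths) != 1:
        raise ValueError("aligned rows must have equal length")
    ncol = lengths.pop()
    rows = [r.upper() for r in alignment]
    max_ic = math.log2(20.0)

    info = np.zeros(ncol)
    occ = np.zeros(ncol)
    heights = np.zeros((ncol, 20))
    for j in range(ncol):
        col = [r[j] for r in rows]
        counts = np.zeros(20)
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        n = counts.sum()
        occ[j] = n / len(col)
        if n == 0:
            continue
        freqs = counts / n
        nz = freqs > 0
        entropy = -np.sum(freqs[nz] * np.log2(freqs[nz]))
        ic = max_ic - entropy
        if corrections == "small_sample":
            ic = max(ic - 19.0 / (2.0 * math.log(2.0) * n), 0.0)
        info[j] = ic
        heights[j] = freqs * ic * occ[j]
    categories = (
        list(site_category) if site_category is not None else ["none"] * ncol
    )
    if len(categories) != ncol:
        raise ValueError("site_category must have one entry per column")
    return LogoMatrix(
        information=info, heights=heights, occupancy=occ, site_category=categories
    )


# ---------------------------------------------------------------------------
# structure proximity and mapping


def annotate_proximity(
    structure, ligand_selection: dict, cutoff: float = 5.0
) -> dict:
    """Protein residues with any heavy atom within ``cutoff`` of a ligand.

    ``structure`` is a biotite AtomArray (e.g. from a PDB file);
    ``ligand_selection`` maps group names (e.g. "active", "allosteric") to
    lists of HETATM residue names.  A residue is included iff any of its
    non-hydrogen atoms lies at distance <= cutoff (inclusive boundary) from
    any atom of the group.  Returns {group: sorted residue ids}.
    """
    from scipy.spatial import cKDTree

    if not ligand_selection:
        raise ValueError("ligand selection must be non-empty")
    protein = structure[~structure.hetero]
    heavy = protein[protein.element != "H"]
    if heavy.array_length() == 0:
        raise ValueError("structure contains no protein atoms")
    tree = cKDTree(heavy.coord)
    out = {}
    for group, resnames in ligand_selection.items():
        lig = structure[structure.hetero & np.isin(structure.res_name, resnames)]
        if lig.array_length() == 0:
            raise ValueError(f"ligand selection {group!r} ({resnames}) matched nothing")
        idx = tree.query_ball_point(lig.coord, r=cutoff)
        hits = sorted({int(heavy.res_id[i]) for lst in idx for i in lst})
        out[group] = hits
    return out


def map_structure_to_alignment(
    structure_sequence: str,
    alignment: Sequence[str],
    min_identity: float = 0.3,
) -> tuple[dict, int, list]:
    """Map structure residue numbers to alignment columns.

    The structure sequence is globally aligned to every alignment row
    (gaps stripped); the row with the highest identity anchors the mapping.
    Returns ``(residue_to_column, best_row_index, unmapped_residues)`` with
    1-based residue numbers and 0-based alignment columns.  Raises if the
    best identity falls below ``min_identity``.
    """
    if not alignment:
        raise ValueError("empty alignment")
    best_row, best_id = None, -1.0
    for r, row in enumerate(alignment):
        ungapped = "".join(c for c in row if c not in GAP_CHARS)
        if not ungapped:
            continue
        ident = pairwise_identity(structure_sequence, ungapped)
        if ident > best_id:
            best_id, best_row = ident, r
    if best_row is None or best_id < min_identity:
        raise ValueError(
            f"no alignment row reaches identity {min_identity} "
            f"(best {best_id:.2f}); mapping failed"
        )
    row = alignment[best_row]
    ungapped = "".join(c for c in row if c not in GAP_CHARS)
    # residue index in the ungapped row -> alignment column
    row_pos_to_col = [j for j, c in enumerate(row) if c not in GAP_CHARS]

    aligner = _identity_aligner()
    aln = aligner.align(structure_sequence.upper(), ungapped.upper())[0]
    mapping: dict[int, int] = {}
    unmapped: list[int] = []
    si = ri = 0
    for cs, cr in zip(aln[0], aln[1]):
        s_gap, r_gap = cs in GAP_CHARS, cr in GAP_CHARS
        if not s_gap and not r_gap:
            mapping[si + 1] = row_pos_to_col[ri]
        if not s_gap and r_gap:
            unmapped.append(si + 1)
        si += 0 if s_gap else 1
        ri += 0 if r_gap else 1
    return mapping, best_row, unmapped
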