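"""Neuropeptide-precursor candidate discovery from a proteome.

Secreted proteins (external signal-peptide calls, or a documented built-in
heuristic stand-in) are scanned downstream of the signal peptide for
prohormone-convertase cleavage motifs: dibasic sites (KR/RR/KK/RK) and
monobasic K/R sites with a basic residue exactly 2, 4, or 6 residues
upstream. The inter-site segments are the candidate mature peptides; a
glycine immediately before a downstream cleavage site marks C-terminal
amidation. Candidates are ranked by peptide count, amidation count, and
internal peptide similarity — a stand-in for the manual curation a real
neuropeptide catalog requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_core import read_tsv_table

__all__ = [
    "SignalCall",
    "CleavageSite",
    "Peptide",
    "PrecursorCandidate",
    "call_signal_peptide",
    "find_cleavage_sites",
    "extract_peptides",
    "rank_candidates",
    "scan_proteome",
    "read_signal_calls",
    "conservation_audit",
]

BASIC = frozenset("KR")

# Kyte-Doolittle hydropathy
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

HEURISTIC_WINDOW = 8
HEURISTIC_HYDROPATHY = 1.6
HEURISTIC_SCAN_END = 45  # 1-based; cleavage_pos of heuristic calls stays <= 45
DEFAULT_SIGNAL_END = 22  # typical signal-peptide length when no position is known
SIGNALP_D_CUTOFF = 0.34


@dataclass
class SignalCall:
    """Secretion call for one protein; cleavage_pos is the 1-based index of
    the last signal-peptide residue (present only when secreted)."""

    protein_id: str
    is_secreted: bool
    cleavage_pos: int | None = None


@dataclass
class CleavageSite:
    position: int  # 1-based index of the first residue of the motif
    motif_class: str  # "dibasic" or "monobasic"

    @property
    def span(self) -> int:
        return 2 if self.motif_class == "dibasic" else 1


@dataclass
class Peptide:
    start: int  # 1-based, inclusive, on the precursor
    end: int
    sequence: str
    amidated: bool


@dataclass
class PrecursorCandidate:
    protein_id: str
    is_secreted: bool
    signal_end: int
    sites: list[CleavageSite] = field(default_factory=list)
    peptides: list[Peptide] = field(default_factory=list)
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    n_oversize: int = 0

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_amidated(self) -> int:
        return sum(p.amidated for p in self.peptides)


def call_signal_peptide(seq: str, protein_id: str = "") -> SignalCall:
    """Heuristic secretion call: a crude stand-in for a dedicated predictor.

    Scans length-8 windows inside the first 45 residues; the protein is
    called secreted when some window has mean Kyte-Doolittle hydropathy
    >= 1.6 (the hydrophobic h-region) and the first five residues contain a
    basic K/R or the initial methionine (the n-region). The inferred
    cleavage position is the end of the best window + 3. External call
    tables always override this heuristic.
    """
    seq = seq.upper()
    if len(seq) < 30:
        return SignalCall(protein_id, False)
    n_region_ok = seq[0] == "M" or any(c in BASIC for c in seq[:5])
    best_mean, best_end = None, None
    # window must fit so that end + 3 <= 45 (1-based)
    last_start = min(len(seq) - HEURISTIC_WINDOW, HEURISTIC_SCAN_END - HEURISTIC_WINDOW - 3)
    for s in range(0, last_start + 1):
        window = seq[s : s + HEURISTIC_WINDOW]
        mean = sum(KD.get(c, 0.0) for c in window) / HEURISTIC_WINDOW
        if best_mean is None or mean > best_mean:
            best_mean, best_end = mean, s + HEURISTIC_WINDOW  # 1-based end
    if n_region_ok and best_mean is not None and best_mean >= HEURISTIC_HYDROPATHY:
        return SignalCall(protein_id, True, cleavage_pos=best_end + 3)
    return SignalCall(protein_id, False)


def find_cleavage_sites(seq: str, signal_end: int) -> list[CleavageSite]:
    """Cleavage motifs downstream of the signal peptide.

    Dibasic sites are consecutive K/R pairs, resolved left-to-right without
    residue re-use; monobasic sites are remaining K/R residues preceded by
    another free K/R (one not already consumed by a dibasic site, so a basic
    residue inside a mature peptide adjacent to a dibasic site does not
    trigger cleavage) exactly 2, 4, or 6 residues upstream. Positions are
    1-based indices of the first motif residue.
    """
    if signal_end >= len(seq):
        raise ValueError("signal_end must lie before the end of the sequence")
    seq = seq.upper()
    n = len(seq)
    dibasic: list[int] = []
    consumed: set[int] = set()
    i = signal_end  # 0-based scan start, first residue after the signal
    while i < n - 1:
        if seq[i] in BASIC and seq[i + 1] in BASIC:
            dibasic.append(i)
            consumed.update((i, i + 1))
            i += 2
        else:
            i += 1
    mono: list[int] = []
    for j in range(signal_end, n):
        if seq[j] not in BASIC or j in consumed:
            continue
        if any(
            j - s >= 0 and seq[j - s] in BASIC and (j - s) not in consumed
            for s in (2, 4, 6)
        ):
            mono.append(j)
    sites = [CleavageSite(p + 1, "dibasic") for p in dibasic]
    sites += [CleavageSite(p + 1, "monobasic") for p in mono]
    sites.sort(key=lambda s: s.position)
    return sites


def extract_peptides(
    seq: str,
    signal_end: int,
    sites: list[CleavageSite],
    min_len: int = 3,
    max_len: int = 40,
    protein_id: str = "",
    is_secreted: bool = True,
) -> PrecursorCandidate:
    """Enumerate candidate mature peptides between cleavage sites.

    Peptides are the inter-site segments: bounded on the left by the signal
    peptide or a cleavage site and on the right by a cleavage site (the
    unbounded C-terminal tail is never a peptide, so zero sites yield zero
    peptides). Each segment is trimmed of a C-terminal glycine when it
    immediately precedes the downstream site (amidation signal, recorded)
    and of flanking basic residues, then kept when
    min_len <= length <= max_len. Every residue of the post-signal sequence
    is accounted for in ``segments`` so the conservation audit can
    reconstitute it exactly.
    """
    seq = seq.upper()
    n = len(seq)
    cand = PrecursorCandidate(protein_id, is_secreted, signal_end, list(sites))
    occupied = [False] * n
    for s in sites:
        for j in range(s.position - 1, s.position - 1 + s.span):
            occupied[j] = True
        cand.segments.append((s.position - 1, s.position - 1 + s.span, "site"))

    j = signal_end
    while j < n:
        if occupied[j]:
            j += 1
            continue
        start = j
        while j < n and not occupied[j]:
            j += 1
        end = j  # raw segment [start, end)
        if end == n or not occupied[end]:
            # no downstream cleavage site: C-terminal tail, not a peptide
            cand.segments.append((start, end, "tail"))
            continue
        seg_end = end
        amidated = False
        if seq[seg_end - 1] == "G" and seg_end > start:
            amidated = True
            cand.segments.append((seg_end - 1, seg_end, "amide_g"))
            seg_end -= 1
        # trim flanking basic residues
        lo, hi = start, seg_end
        while lo < hi and seq[lo] in BASIC:
            cand.segments.append((lo, lo + 1, "flank_basic"))
            lo += 1
        while hi > lo and seq[hi - 1] in BASIC:
            cand.segments.append((hi - 1, hi, "flank_basic"))
            hi -= 1
        length = hi - lo
        if length == 0:
            continue
        if min_len <= length <= max_len:
            cand.peptides.append(Peptide(lo + 1, hi, seq[lo:hi], amidated))
            cand.segments.append((lo, hi, "peptide"))
        else:
            if length > max_len:
                cand.n_oversize += 1
                cand.segments.append((lo, hi, "discard_long"))
            else:
                cand.segments.append((lo, hi, "discard_short"))
    cand.segments.sort()
    return cand


def conservation_audit(seq: str, cand: PrecursorCandidate) -> bool:
    """Segments must tile the post-signal sequence exactly, without overlap.

    Vacuously true for non-secreted proteins, which are never scanned.
    """
    if not cand.is_secreted and not cand.segments:
        return True
    seq = seq.upper()
    pos = cand.signal_end
    for start, end, _kind in cand.segments:
        if start != pos or end <= start:
            return False
        pos = end
    if pos != len(seq):
        return False
    rebuilt = "".join(seq[s:e] for s, e, _ in cand.segments)
    return rebuilt == seq[cand.signal_end :]


def _best_overlap_identity(p: str, q: str) -> float:
    """Identity fraction of the best gap-free overlap alignment of two peptides."""
    best = 0.0
    min_overlap = min(3, len(p), len(q))
    for offset in range(-(len(q) - 1), len(p)):
        lo_p = max(0, offset)
        hi_p = min(len(p), offset + len(q))
        if hi_p - lo_p < min_overlap:
            continue
        matches = sum(
            1 for i in range(lo_p, hi_p) if p[i] == q[i - offset]
        )
        best = max(best, matches / (hi_p - lo_p))
    return best


def peptide_similarity(cand: PrecursorCandidate) -> float:
    """Max pairwise gap-free identity among a candidate's peptides."""
    peps = [p.sequence for p in cand.peptides]
    best = 0.0
    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            best = max(best, _best_overlap_identity(peps[i], peps[j]))
    return best


def rank_candidates(
    candidates: list[PrecursorCandidate], min_peptides: int = 2
) -> pd.DataFrame:
    """Ranked precursor report.

    Keeps secreted candidates with at least ``min_peptides`` peptides and
    ranks by (n_peptides, n_amidated, max pairwise peptide similarity)
    lexicographically descending; protein id breaks exact ties.
    """
    rows = []
    for cand in candidates:
        if not cand.is_secreted or cand.n_peptides < min_peptides:
            continue
        rows.append(
            {
                "protein_id": cand.protein_id,
                "n_peptides": cand.n_peptides,
                "n_amidated": cand.n_amidated,
                "peptide_similarity": peptide_similarity(cand),
                "n_sites": len(cand.sites),
                "signal_end": cand.signal_end,
            }
        )
    cols = [
        "protein_id",
        "n_peptides",
        "n_amidated",
        "peptide_similarity",
        "n_sites",
        "signal_end",
    ]
    report = pd.DataFrame(rows, columns=cols)
    if not report.empty:
        report = report.sort_values(
            ["n_peptides", "n_amidated", "peptide_similarity", "protein_id"],
            ascending=[False, False, False, True],
        ).reset_index(drop=True)
    return report


def read_signal_calls(path) -> dict[str, SignalCall]:
    """Read an external signal-peptide call table (TSV).

    Columns: protein_id plus either is_secreted (0/1) or d_score (rows with
    d_score below 0.34 are treated as non-secreted, matching a sensitive
    D-cutoff); optional cleavage_pos.
    """
    df = read_tsv_table(path)
    calls: dict[str, SignalCall] = {}
    for _, row in df.iterrows():
        pid = str(row["protein_id"])
        if "is_secreted" in df.columns:
            secreted = bool(row["is_secreted"])
        elif "d_score" in df.columns:
            secreted = float(row["d_score"]) >= SIGNALP_D_CUTOFF
        else:
            raise ValueError("signal-call table needs is_secreted or d_score")
        pos = None
        if secreted and "cleavage_pos" in df.columns and pd.notna(row["cleavage_pos"]):
            pos = int(row["cleavage_pos"])
        calls[pid] = SignalCall(pid, secreted, pos)
    return calls


def scan_proteome(
    proteins: list[tuple[str, str]],
    signal_calls: dict[str, SignalCall] | None = None,
    min_len: int = 3,
    max_len: int = 40,
) -> list[PrecursorCandidate]:
    """Run the full scan over (id, sequence) pairs.

    External signal calls take precedence over the heuristic wherever they
    disagree; secreted calls without a cleavage position fall back to the
    heuristic's position, or a typical signal length when the heuristic
    finds none.
    """
    signal_calls = signal_calls or {}
    out = []
    for pid, seq in proteins:
        call = signal_calls.get(pid) or call_signal_peptide(seq, pid)
        if not call.is_secreted:
            out.append(PrecursorCandidate(pid, False, 0))
            continue
        signal_end = call.cleavage_pos
        if signal_end is None:
            heur = call_signal_peptide(seq, pid)
            signal_end = heur.cleavage_pos or min(DEFAULT_SIGNAL_END, len(seq) - 1)
        signal_end = min(signal_end, len(seq) - 1)
        sites = find_cleavage_sites(seq, signal_end)
        out.append(
            extract_peptides(
                seq, signal_end, sites, min_len, max_len, pid, True
            )
        )
    return out
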