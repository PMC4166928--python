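"""Sequence-quality screening of ancient samples.

Postmortem deamination converts C/G base pairs to T/A, and damage events
are essentially never shared between sequences, so a damaged sequence
shows an excess of private (singleton) variants that look like C→T or
G→A changes.  This module classifies each sequence's singletons as
deamination-consistent or not, tests each ancient sequence's
deamination-consistent fraction against the spectrum expected without
damage (estimated from the modern sequences), and compares per-class GC
content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mitoclock.errors import ValidationError
from mitoclock.io import Alignment, A, C, G, T


@dataclass(frozen=True)
class SingletonProfile:
    """Counts of singletons private to one sequence.

    ``n_deam``: singletons consistent with deamination (the sequence
    carries T where all others carry C, or A where all others carry G);
    ``n_other``: every other singleton carried by the sequence.
    """

    n_deam: int
    n_other: int

    @property
    def total(self) -> int:
        return self.n_deam + self.n_other


def classify_singletons(alignment: Alignment, focal_ids=None) -> dict:
    """Per-sequence singleton profiles.

    A column is a singleton for sequence i iff, ignoring rows that are
    ambiguous (N or gap) in that column, exactly one row (i) differs from
    the single shared state of all the others.  Columns with more than two
    distinct unambiguous states contribute to no profile.
    """
    if alignment.n_sequences < 3:
        raise ValidationError("singletons need at least 3 sequences")
    focal = set(focal_ids) if focal_ids is not None else set(alignment.ids)
    unknown = focal - set(alignment.ids)
    if unknown:
        raise ValidationError(f"unknown focal ids {sorted(unknown)}")

    codes = alignment.codes
    onehot = np.stack([(codes == s) for s in (A, C, G, T)])  # (4, rows, cols)
    counts = onehot.sum(axis=1)  # (4, cols)
    present = counts > 0
    n_states = present.sum(axis=0)
    unambig = counts.sum(axis=0)
    # biallelic columns whose minority allele is carried by exactly one row
    # (and the majority by at least two, so 'all the others' is meaningful)
    cand = (n_states == 2) & (counts.min(axis=0, where=present, initial=np.iinfo(np.int64).max) == 1)
    cand &= (unambig >= 3)

    n_deam = dict.fromkeys(alignment.ids, 0)
    n_other = dict.fromkeys(alignment.ids, 0)
    deam_pairs = {(C, T), (G, A)}  # (majority, focal)
    for col in np.flatnonzero(cand):
        cc = counts[:, col]
        states = np.flatnonzero(cc)
        minor, major = sorted(states, key=lambda s: cc[s])
        if cc[minor] != 1 or cc[major] < 2:
            continue
        row = int(np.flatnonzero(onehot[minor, :, col])[0])
        sid = alignment.ids[row]
        if sid not in focal:
            continue
        if (major, minor) in deam_pairs:
            n_deam[sid] += 1
        else:
            n_other[sid] += 1
    return {
        sid: SingletonProfile(n_deam[sid], n_other[sid])
        for sid in alignment.ids
        if sid in focal
    }


def pooled_reference_fraction(profiles: dict) -> float:
    """Deamination-consistent fraction of the pooled singleton spectrum."""
    deam = sum(p.n_deam for p in profiles.values())
    total = sum(p.total for p in profiles.values())
    if total == 0:
        raise ValidationError("no singletons in the reference set")
    return deam / total


@dataclass(frozen=True)
class DamageTestResult:
    sample_id: str
    n_deam: int
    n_other: int
    statistic: float  # observed deamination-consistent fraction
    p_value: float
    flagged: bool


def damage_excess_test(profiles: dict, reference_fraction: float,
                       alpha: float = 0.05, bonferroni: bool = True) -> dict:
    """Two-sided exact binomial test of each profile against the reference.

    A sequence is flagged iff its (Bonferroni-corrected, by default)
    p-value is below ``alpha`` AND its deamination-consistent fraction
    exceeds the reference (excess, not deficit).  Zero singletons give
    p = 1 and no flag.
    """
    if not (0 < reference_fraction < 1):
        raise ValidationError("reference_fraction must be in (0, 1)")
    m = max(1, len(profiles))
    threshold = alpha / m if bonferroni else alpha
    out = {}
    for sid, p in profiles.items():
        if p.total == 0:
            out[sid] = DamageTestResult(sid, 0, 0, np.nan, 1.0, False)
            continue
        test = stats.binomtest(p.n_deam, p.total, reference_fraction,
                               alternative="two-sided")
        frac = p.n_deam / p.total
        flagged = bool(test.pvalue < threshold and frac > reference_fraction)
        out[sid] = DamageTestResult(sid, p.n_deam, p.n_other, frac,
                                    float(test.pvalue), flagged)
    return out


def pooled_damage_test(profiles: dict, reference_fraction: float):
    """One exact binomial test on the pooled profile of a set of sequences."""
    deam = sum(p.n_deam for p in profiles.values())
    total = sum(p.total for p in profiles.values())
    if total == 0:
        return np.nan, 1.0
    test = stats.binomtest(deam, total, reference_fraction, alternative="two-sided")
    return deam / total, float(test.pvalue)


@dataclass(frozen=True)
class BaseCompositionResult:
    class_a: str
    class_b: str
    mean_gc_difference: float  # mean GC(a) - mean GC(b)
    t_statistic: float
    p_value: float
    testable: bool


def gc_fraction(alignment: Alignment) -> np.ndarray:
    """Per-sequence GC fraction; gaps and Ns excluded from the denominator."""
    codes = alignment.codes
    gc = ((codes == G) | (codes == C)).sum(axis=1)
    acgt = (codes <= T).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(acgt > 0, gc / np.maximum(acgt, 1), np.nan)


def base_composition_test(alignment: Alignment, groups: dict) -> dict:
    """Welch unpaired t-test of per-sequence GC content between classes.

    ``groups`` maps sequence id to a class label.  Classes with fewer than
    two members, or with zero variance in both classes, are reported as
    not testable.
    """
    gcs = gc_fraction(alignment)
    by_class: dict = {}
    for i, sid in enumerate(alignment.ids):
        if sid in groups:
            by_class.setdefault(groups[sid], []).append(gcs[i])
    labels = sorted(by_class)
    out = {}
    for ai in range(len(labels)):
        for bi in range(ai + 1, len(labels)):
            a, b = labels[ai], labels[bi]
            xa, xb = np.asarray(by_class[a]), np.asarray(by_class[b])
            diff = float(np.mean(xa) - np.mean(xb)) if len(xa) and len(xb) else np.nan
            if len(xa) < 2 or len(xb) < 2 or (np.var(xa) == 0 and np.var(xb) == 0):
                out[(a, b)] = BaseCompositionResult(a, b, diff, np.nan, np.nan, False)
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            out[(a, b)] = BaseCompositionResult(a, b, diff, float(t), float(p), True)
    return out


def qc_report(alignment: Alignment, samples, alpha: float = 0.05) -> pd.DataFrame:
    """End-to-end QC table for a panel: singleton damage test per ancient tip.

    The reference fraction comes from the pooled singleton spectrum of the
    modern sequences; outgroup rows are excluded from the scan entirely.
    """
    by_id = {s.sample_id: s for s in samples}
    keep = [sid for sid in alignment.ids
            if sid in by_id and by_id[sid].sample_class.value != "outgroup"]
    aln = alignment.subset_sequences(keep)
    profiles = classify_singletons(aln)
    modern = {sid: p for sid, p in profiles.items()
              if by_id[sid].sample_class.value == "modern"}
    ancient = {sid: p for sid, p in profiles.items() if by_id[sid].is_ancient}
    ref = pooled_reference_fraction(modern)
    results = damage_excess_test(ancient, ref, alpha=alpha)
    rows = [
        {
            "sample_id": r.sample_id,
            "n_deam": r.n_deam,
            "n_other": r.n_other,
            "deam_fraction": r.statistic,
            "p_value": r.p_value,
            "flagged": r.flagged,
        }
        for r in results.values()
    ]
    df = pd.DataFrame(rows)
    df.attrs["reference_fraction"] = ref
    return df
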