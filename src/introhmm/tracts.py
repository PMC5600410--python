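"""Tract construction, the seven-filter cleanup pipeline, and region merging.

Raw tracts are maximal runs of markers sharing the same most-probable HMM
state.  A cascade of seven ordered filters then (1) merges adjacent
heterozygous/homozygous-donor tracts, (2) demotes weakly supported
introgression tracts surrounded by error tracts, (3-5) resolves error tracts
to the recipient background or into flanking introgressions, (6) absorbs
tiny recipient gaps splitting large introgressions, and (7) re-applies the
first merge.  Reported introgressions additionally satisfy minimum length,
minimum introgression-SNP count and maximum repeat-content rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hmm import (HET, HOMO_D, HOMO_R, N_STATES, STATE_NAMES, StatePosteriors)

INTROGRESSION = (HET, HOMO_D)


def _is_intro(state: int) -> bool:
    return state in INTROGRESSION


def _is_error(state: int) -> bool:
    return state >= 3


@dataclass
class Tract:
    """A maximal run of markers in one state for one individual.

    start/end are the 1-based positions of the first and last marker of the
    run (inclusive); length = end - start + 1.  ``n_introgression_snps``
    counts markers whose posterior mass on the het + homo_d states is >= 0.5.
    """

    chrom: str
    start: int
    end: int
    state: int
    n_snps: int
    n_introgression_snps: int
    line: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")
        if self.n_introgression_snps > self.n_snps:
            raise ValueError("introgression SNPs exceed total SNPs")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]


@dataclass
class IntrogressionRegion:
    """Union of overlapping per-line introgression tracts.

    ``blocks`` decompose the region at every member-tract endpoint; each
    block carries the set of lines whose tract covers it.
    """

    chrom: str
    start: int
    end: int
    members: frozenset[str]
    frequency: float
    blocks: list[tuple[int, int, frozenset[str]]] = field(default_factory=list)


def build_raw_tracts(posteriors: StatePosteriors,
                     line: str | None = None) -> list[Tract]:
    """Combine adjacent markers with identical most-probable states."""
    states = posteriors.states
    if states.size == 0:
        return []
    pos = posteriors.pos
    p_intro = posteriors.posteriors[:, HET] + posteriors.posteriors[:, HOMO_D]
    is_isnp = p_intro >= 0.5
    bounds = np.flatnonzero(np.diff(states) != 0) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [states.size]])
    return [
        Tract(
            chrom=posteriors.chrom,
            start=int(pos[s]),
            end=int(pos[e - 1]),
            state=int(states[s]),
            n_snps=int(e - s),
            n_introgression_snps=int(is_isnp[s:e].sum()),
            line=line,
        )
        for s, e in zip(starts, ends)
    ]


def _merge_group(group: list[Tract], state: int) -> Tract:
    return Tract(
        chrom=group[0].chrom,
        start=min(t.start for t in group),
        end=max(t.end for t in group),
        state=state,
        n_snps=sum(t.n_snps for t in group),
        n_introgression_snps=sum(t.n_introgression_snps for t in group),
        line=group[0].line,
    )


def _majority_state(group: list[Tract], by: str = "n_introgression_snps") -> int:
    """het vs homo_d by the larger per-label sum of ``by``; ties -> het."""
    het_sum = sum(getattr(t, by) for t in group if t.state == HET)
    d_sum = sum(getattr(t, by) for t in group if t.state == HOMO_D)
    return HOMO_D if d_sum > het_sum else HET


def _coalesce(tracts: list[Tract]) -> list[Tract]:
    out: list[Tract] = []
    for t in tracts:
        if out and out[-1].state == t.state:
            out[-1] = _merge_group([out[-1], t], t.state)
        else:
            out.append(t)
    return out


def _check_ordered(tracts: list[Tract]) -> None:
    for a, b in zip(tracts, tracts[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping tracts at {a.chrom}:{a.end}/{b.start}")


def _filter1_merge_intro(tracts: list[Tract]) -> list[Tract]:
    out: list[Tract] = []
    i = 0
    while i < len(tracts):
        if _is_intro(tracts[i].state):
            j = i
            while j < len(tracts) and _is_intro(tracts[j].state):
                j += 1
            group = tracts[i:j]
            out.append(_merge_group(group, _majority_state(group)))
            i = j
        else:
            out.append(tracts[i])
            i += 1
    return _coalesce(out)


def _filter2_demote_small_intro(tracts: list[Tract],
                                min_isnps: int = 15,
                                min_ratio: float = 3.0) -> list[Tract]:
    """Reassign weak introgression tracts inside error neighbourhoods.

    A het/homo_d tract becomes its error twin when it has fewer than
    ``min_isnps`` introgression SNPs and its introgression-SNP count divided
    by the total SNPs of the error runs immediately left and right is below
    ``min_ratio``.  With no adjacent error run the filter does not apply.
    """
    n = len(tracts)
    new_states = [t.state for t in tracts]
    for i, t in enumerate(tracts):
        if not _is_intro(t.state) or t.n_introgression_snps >= min_isnps:
            continue
        adj = 0
        j = i - 1
        while j >= 0 and _is_error(tracts[j].state):
            adj += tracts[j].n_snps
            j -= 1
        j = i + 1
        while j < n and _is_error(tracts[j].state):
            adj += tracts[j].n_snps
            j += 1
        if adj > 0 and t.n_introgression_snps / adj < min_ratio:
            new_states[i] = t.state + 3
    out = [replace(t, state=s) for t, s in zip(tracts, new_states)]
    return _coalesce(out)


def _error_runs(tracts: list[Tract]):
    """Yield (i, j) with tracts[i:j] a maximal run of error-state tracts."""
    i = 0
    n = len(tracts)
    while i < n:
        if _is_error(tracts[i].state):
            j = i
            while j < n and _is_error(tracts[j].state):
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _filter3_error_in_homo_r(tracts: list[Tract]) -> list[Tract]:
    new_states = [t.state for t in tracts]
    for i, j in _error_runs(tracts):
        if (i > 0 and tracts[i - 1].state == HOMO_R
                and j < len(tracts) and tracts[j].state == HOMO_R):
            for idx in range(i, j):
                new_states[idx] = HOMO_R
    return _coalesce([replace(t, state=s)
                      for t, s in zip(tracts, new_states)])


def _filter4_error_in_intro(tracts: list[Tract]) -> list[Tract]:
    """Error runs bounded by introgression tracts merge into one tract."""
    while True:
        merged = False
        out: list[Tract] = []
        i = 0
        n = len(tracts)
        while i < n:
            t = tracts[i]
            if (_is_error(t.state) and out and _is_intro(out[-1].state)):
                j = i
                while j < n and _is_error(tracts[j].state):
                    j += 1
                if j < n and _is_intro(tracts[j].state):
                    group = [out.pop()] + tracts[i:j + 1]
                    state = _majority_state(group)
                    out.append(_merge_group(group, state))
                    i = j + 1
                    merged = True
                    continue
            out.append(t)
            i += 1
        tracts = _coalesce(out)
        if not merged:
            return tracts


def _filter5_error_to_homo_r(tracts: list[Tract]) -> list[Tract]:
    return _coalesce([
        replace(t, state=HOMO_R) if _is_error(t.state) else t
        for t in tracts
    ])


def _filter6_small_homo_r(tracts: list[Tract], max_gap_snps: int = 5,
                          min_flank_snps: int = 10) -> list[Tract]:
    """Absorb tiny homo_r gaps splitting well-supported introgressions.

    The flanking requirement uses total SNP counts, and the merged label is
    the flank with more total SNPs (ties -> het).
    """
    while True:
        merged = False
        out: list[Tract] = []
        i = 0
        n = len(tracts)
        while i < n:
            t = tracts[i]
            if (t.state == HOMO_R and t.n_snps < max_gap_snps
                    and out and _is_intro(out[-1].state)
                    and out[-1].n_snps >= min_flank_snps
                    and i + 1 < n and _is_intro(tracts[i + 1].state)
                    and tracts[i + 1].n_snps >= min_flank_snps):
                group = [out.pop(), t, tracts[i + 1]]
                state = _majority_state(group, by="n_snps")
                out.append(_merge_group(group, state))
                i += 2
                merged = True
                continue
            out.append(t)
            i += 1
        tracts = _coalesce(out)
        if not merged:
            return tracts


def filter_tracts(raw: list[Tract]) -> list[Tract]:
    """Apply the seven cleanup filters, in order, to one chromosome's tracts.

    The output contains no error-state tracts and no two adjacent tracts
    with the same label; total marker counts are conserved.  The pipeline is
    idempotent.
    """
    if not raw:
        return []
    _check_ordered(raw)
    tracts = _filter1_merge_intro(list(raw))
    tracts = _filter2_demote_small_intro(tracts)
    tracts = _filter3_error_in_homo_r(tracts)
    tracts = _filter4_error_in_intro(tracts)
    tracts = _filter5_error_to_homo_r(tracts)
    tracts = _filter6_small_homo_r(tracts)
    tracts = _filter1_merge_intro(tracts)
    return tracts


def repeat_fraction(tract: Tract, repeats: dict[str, np.ndarray]) -> float:
    """Fraction of the tract span covered by repeat intervals.

    ``repeats`` maps chromosome -> (N, 2) array of 1-based inclusive,
    sorted, non-overlapping intervals.
    """
    iv = repeats.get(tract.chrom)
    if iv is None or len(iv) == 0:
        return 0.0
    iv = np.asarray(iv)
    lo = np.maximum(iv[:, 0], tract.start)
    hi = np.minimum(iv[:, 1], tract.end)
    return float(np.clip(hi - lo + 1, 0, None).sum()) / tract.length


def reporting_filter(
    tracts: list[Tract],
    repeats: dict[str, np.ndarray] | None = None,
    min_len: int = 500,
    min_snps: int = 10,
    max_repeat_frac: float = 0.3,
) -> list[Tract]:
    """Keep reportable introgression tracts.

    Retains het/homo_d tracts spanning at least ``min_len`` bp with at least
    ``min_snps`` introgression SNPs and at most ``max_repeat_frac`` of the
    span inside annotated repeats.  With no repeat annotation the repeat
    rule is skipped (with a warning).
    """
    import warnings

    if repeats is None:
        warnings.warn("no repeat annotation supplied; repeat-content rule "
                      "skipped")
    out = []
    for t in tracts:
        if not _is_intro(t.state):
            continue
        if t.length < min_len or t.n_introgression_snps < min_snps:
            continue
        if repeats is not None and \
                repeat_fraction(t, repeats) > max_repeat_frac:
            continue
        out.append(t)
    return out


def merge_regions(per_line_tracts: dict[str, list[Tract]],
                  n_lines: int) -> list[IntrogressionRegion]:
    """Single-linkage merge of overlapping tracts across lines into regions.

    Within each region, breakpoints at every member-tract endpoint define
    blocks annotated with their member sets; frequency = distinct member
    lines / ``n_lines``.
    """
    tagged: list[Tract] = []
    for line, tracts in per_line_tracts.items():
        for t in tracts:
            tagged.append(replace(t, line=line))
    regions: list[IntrogressionRegion] = []
    by_chrom: dict[str, list[Tract]] = {}
    for t in tagged:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in sorted(by_chrom.items()):
        ts.sort(key=lambda t: (t.start, t.end))
        i = 0
        while i < len(ts):
            group = [ts[i]]
            end = ts[i].end
            j = i + 1
            while j < len(ts) and ts[j].start <= end:
                group.append(ts[j])
                end = max(end, ts[j].end)
                j += 1
            members = frozenset(t.line for t in group)
            start = min(t.start for t in group)
            cuts = sorted({t.start for t in group} | {t.end + 1 for t in group})
            blocks = []
            for lo, hi in zip(cuts, cuts[1:]):
                cover = frozenset(t.line for t in group
                                  if t.start <= lo and t.end >= hi - 1)
                if cover:
                    blocks.append((lo, hi - 1, cover))
            regions.append(IntrogressionRegion(
                chrom=chrom, start=start, end=end, members=members,
                frequency=len(members) / n_lines, blocks=blocks,
            ))
            i = j
    return regions


def read_repeats_bed(path) -> dict[str, np.ndarray]:
    """Load a BED file of repeat intervals into 1-based inclusive arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            by_chrom.setdefault(f[0], []).append((int(f[1]) + 1, int(f[2])))
    return {c: np.array(sorted(iv), dtype=np.int64)
            for c, iv in by_chrom.items()}


def tracts_to_frame(tracts: list[Tract]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": t.chrom, "start": t.start, "end": t.end,
                "line": t.line, "state": t.state_name,
                "n_snps": t.n_snps,
                "n_introgression_snps": t.n_introgression_snps,
            }
            for t in tracts
        ],
        columns=["chrom", "start", "end", "line", "state", "n_snps",
                 "n_introgression_snps"],
    )


def write_tracts_tsv(tracts: list[Tract], path, bed: bool = False) -> None:
    """Native 1-based TSV, or BED-like 0-based half-open with ``bed=True``."""
    df = tracts_to_frame(tracts)
    if bed:
        df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", index=False, header=not bed)
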