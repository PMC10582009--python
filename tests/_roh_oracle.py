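"""Brute-force ROH reference implementation for oracle-equivalence tests.

Deliberately naive: enumerates every scanning window and every candidate run
with explicit Python loops, independently of the vectorised caller.
"""

from erosure.roh import ROHParams, ROHSegment


def brute_force_roh(sample_id, chrom, pos, gt, params: ROHParams):
    """Return ROHSegment list for one sample on one chromosome."""
    n = len(pos)
    w = params.window_snp

    # window i covers SNP indices [i, i+w); homozygous iff few het/missing
    hom_windows = []
    for i in range(max(n - w + 1, 0)):
        window = gt[i : i + w]
        n_het = sum(1 for x in window if x == 1)
        n_mis = sum(1 for x in window if x == -1)
        hom_windows.append(
            n_het <= params.window_het and n_mis <= params.window_missing
        )

    passing = []
    for j in range(n):
        covering = [
            hom_windows[i]
            for i in range(len(hom_windows))
            if i <= j < i + w
        ]
        if not covering:
            passing.append(False)
        else:
            frac = sum(covering) / len(covering)
            passing.append(frac >= params.window_threshold)

    # maximal runs of passing SNPs, split at oversized gaps
    runs = []
    cur = None
    for j in range(n):
        if not passing[j]:
            if cur is not None:
                runs.append(cur)
                cur = None
            continue
        if cur is None:
            cur = [j, j]
        elif pos[j] - pos[cur[1]] > params.max_gap_kb * 1000:
            runs.append(cur)
            cur = [j, j]
        else:
            cur[1] = j
    if cur is not None:
        runs.append(cur)

    segments = []
    for s, e in runs:
        span = pos[e] - pos[s] + 1
        n_snps = e - s + 1
        n_het = sum(1 for x in gt[s : e + 1] if x == 1)
        if span < params.min_kb * 1000:
            continue
        if n_snps < params.min_snp:
            continue
        if span / 1000.0 / n_snps > params.density_kb_per_snp:
            continue
        if n_het > params.max_het_in_segment:
            continue
        segments.append(
            ROHSegment(sample_id, chrom, int(pos[s]), int(pos[e]), n_snps, n_het)
        )
    return segments
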