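"""Independent brute-force oracles for the detectors.

These are deliberately literal, O(n^2)-tolerant transcriptions of the
detection rules, kept free of the vectorised implementation's machinery
so agreement between the two is meaningful.
"""

from __future__ import annotations

from spikewell.bursts import BurstParams


def brute_force_bursts(times, params: BurstParams):
    """Literal max-interval rules: begin, extend, merge, filter.

    Returns (start_time, end_time, n_spikes) tuples.  Spike membership of
    a merged burst is interval membership (all spikes between merged
    start and end), matching the detector's convention.
    """
    t = list(times)
    n = len(t)
    # rules 1-2: candidate bursts as (first spike idx, last spike idx)
    candidates = []
    i = 0
    while i < n - 1:
        if t[i + 1] - t[i] <= params.max_begin_isi_s:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= params.max_end_isi_s:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1
    # rule 3: merge bursts separated by < min_ibi_s (chained)
    merged: list[tuple[int, int]] = []
    for s, e in candidates:
        if merged and t[s] - t[merged[-1][1]] < params.min_ibi_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # rule 4: discard short or small bursts
    out = []
    for s, e in merged:
        if (e - s + 1) >= params.min_spikes and (t[e] - t[s]) >= params.min_duration_s:
            out.append((t[s], t[e], e - s + 1))
    return out


def brute_force_network_spikes(times, electrodes, active_set, bin_s, min_participants):
    """Bin scan: distinct active electrodes per bin, merge adjacent
    qualifying bins.  Returns (start, end, participant frozenset)."""
    bins: dict[int, set] = {}
    for t, e in zip(times, electrodes):
        if e in active_set:
            bins.setdefault(int(t // bin_s), set()).add(e)
    qualifying = sorted(b for b, s in bins.items() if len(s) >= min_participants)
    events = []
    for b in qualifying:
        if events and b == events[-1][1] + 1:
            start, _, parts = events[-1]
            events[-1] = (start, b, parts | bins[b])
        else:
            events.append((b, b, set(bins[b])))
    return [
        (b0 * bin_s, (b1 + 1) * bin_s, frozenset(parts)) for b0, b1, parts in events
    ]


def brute_force_network_bursts(intervals, min_participants):
    """Interval stabbing at every boundary and midpoint.

    ``intervals`` are (start, end, electrode) closed burst intervals.
    Coverage is evaluated at each boundary time and at the midpoint of
    each adjacent boundary pair; maximal runs of qualifying test points
    become events.  Returns (start, end) pairs.
    """
    pts = sorted({x for s, e, _ in intervals for x in (s, e)})
    test_points = []
    for i, b in enumerate(pts):
        test_points.append(b)
        if i + 1 < len(pts):
            test_points.append((b + pts[i + 1]) / 2.0)
    cover = [
        sum(1 for s, e, _ in intervals if s <= x <= e) for x in test_points
    ]
    qual = [c >= min_participants for c in cover]
    out = []
    i = 0
    while i < len(test_points):
        if qual[i]:
            j = i
            while j + 1 < len(test_points) and qual[j + 1]:
                j += 1
            out.append((test_points[i], test_points[j]))
            i = j + 1
        else:
            i += 1
    return out
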