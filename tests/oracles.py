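"""Independent brute-force oracles for event extraction.

Deliberately naive per-frame scans, kept free of any code from
``sociotrack.events`` so the two routes can be compared in tests.
"""

from __future__ import annotations


def oracle_correct_gaps(labels, fps, gap_merge_s=0.5):
    """Per-stimulus left-to-right scan merging strict sub-threshold gaps
    of pure 'none' frames flanked by the stimulus."""
    out = list(labels)
    n = len(out)
    for stim in (1, 2):
        other = 3 - stim
        i = 0
        while i < n:
            if out[i] == stim:
                # find end of this stimulus run
                j = i
                while j < n and out[j] == stim:
                    j += 1
                # gap until the next `stim` frame
                k = j
                while k < n and out[k] != stim:
                    k += 1
                if k < n:
                    gap = out[j:k]
                    if (k - j) / fps < gap_merge_s and other not in gap:
                        for m in range(j, k):
                            out[m] = stim
                i = k
            else:
                i += 1
    return out


def oracle_bouts(labels, fps):
    """(stimulus, start_s, end_s) per maximal non-none run."""
    bouts = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] in (1, 2):
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            bouts.append((int(labels[i]), i / fps, j / fps))
            i = j
        else:
            i += 1
    return bouts


def oracle_transitions(bout_stimuli):
    """Number of stimulus changes in the bout sequence."""
    return sum(1 for a, b in zip(bout_stimuli, bout_stimuli[1:]) if a != b)


def oracle_intervals(bouts, gap_merge_s=0.5):
    """(stimulus, start_s, end_s) gaps strictly longer than gap_merge_s
    between consecutive same-stimulus bouts."""
    out = []
    for stim in (1, 2):
        mine = [b for b in bouts if b[0] == stim]
        for (s0, a0, b0), (s1, a1, b1) in zip(mine, mine[1:]):
            if a1 - b0 > gap_merge_s:
                out.append((stim, b0, a1))
    return sorted(out, key=lambda x: (x[1], x[0]))
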