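"""Independent reference implementations used as test oracles.

These are deliberately naive (sample-by-sample scans, brute-force grids,
textbook formulas) and share no code with the package implementations they
check.
"""

from __future__ import annotations

import numpy as np


def reference_detect(env, fs, threshold_factor=2.0, edge_rule="half_max", threshold=None):
    """Exhaustive sample-scan burst detector.

    Returns a list of dicts with onset_s, offset_s, peak_amplitude,
    peak_time_s, mirroring the contract of ``bursting.detect_bursts``.
    """
    env = list(map(float, env))
    n = len(env)
    if threshold is not None:
        T = float(threshold)
    else:
        T = threshold_factor * float(np.median(env))

    # Collect maximal suprathreshold runs by scanning every sample.
    runs = []
    i = 0
    while i < n:
        if env[i] > T:
            j = i
            while j + 1 < n and env[j + 1] > T:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    spans = []
    for start, end in runs:
        peak_idx = start
        for k in range(start, end + 1):
            if env[k] > env[peak_idx]:
                peak_idx = k
        peak = env[peak_idx]
        if edge_rule == "threshold":
            if start == 0 or end == n - 1:
                continue
            spans.append([start, end, peak, peak_idx])
            continue
        half = peak / 2.0
        left = peak_idx
        while left - 1 >= 0 and env[left - 1] >= half:
            left -= 1
        right = peak_idx
        while right + 1 <= n - 1 and env[right + 1] >= half:
            right += 1
        if left == 0 or right == n - 1:
            continue
        spans.append([left, right, peak, peak_idx])

    if edge_rule == "half_max":
        # Repeatedly merge any pair of spans that touch or overlap.
        changed = True
        while changed:
            changed = False
            spans.sort(key=lambda s: s[0])
            out = []
            for s in spans:
                if out and s[0] <= out[-1][1] + 1:
                    prev = out[-1]
                    prev[1] = max(prev[1], s[1])
                    if s[2] > prev[2]:
                        prev[2], prev[3] = s[2], s[3]
                    changed = True
                else:
                    out.append(s)
            spans = out

    spans.sort(key=lambda s: s[0])
    return [
        {
            "onset_s": s[0] / fs,
            "offset_s": (s[1] + 1) / fs,
            "peak_amplitude": s[2],
            "peak_time_s": s[3] / fs,
        }
        for s in spans
    ]


def reference_summary(onsets, offsets, amplitudes, analyzed_s):
    """Brute-force burst summary: rate and medians."""
    order = sorted(range(len(onsets)), key=lambda i: onsets[i])
    onsets = [onsets[i] for i in order]
    offsets = [offsets[i] for i in order]
    amplitudes = [amplitudes[i] for i in order]
    n = len(onsets)
    rate = n / (analyzed_s / 60.0)
    if n == 0:
        return {"rate": 0.0, "dur": np.nan, "iv": np.nan, "amp": np.nan}
    durations = [b - a for a, b in zip(onsets, offsets)]
    intervals = [onsets[i + 1] - offsets[i] for i in range(n - 1)]
    return {
        "rate": rate,
        "dur": float(np.median(durations)) * 1000.0,
        "iv": float(np.median(intervals)) * 1000.0 if intervals else np.nan,
        "amp": float(np.median(amplitudes)),
    }


def grid_search_gaussian(freqs, flat, centre_grid, height_grid, sigma_grid):
    """Dense grid search for the best single Gaussian on a flattened spectrum."""
    best, best_sse = None, np.inf
    for c in centre_grid:
        for h in height_grid:
            for s in sigma_grid:
                model = h * np.exp(-((freqs - c) ** 2) / (2 * s**2))
                sse = float(np.sum((flat - model) ** 2))
                if sse < best_sse:
                    best_sse, best = sse, (c, h, s)
    return best


def loglog_slope(freqs, power):
    """Plain linear regression of log10 power on log10 frequency."""
    x = np.log10(freqs)
    y = np.log10(power)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return float(slope)


def yates_chi2_textbook(a, b, c, d):
    """Continuity-corrected 2x2 chi-square via the closed-form N(|ad-bc|-N/2)^2 formula."""
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den
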