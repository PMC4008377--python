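"""Independent brute-force oracles for the image statistics.

Everything here is written as explicit Python double loops over pixels and
blocks, deliberately sharing no code with the package implementation.
"""

import math


def intensity_oracle(image, mask):
    """Mean, population SD, min, max of in-mask intensities by pixel loop."""
    vals = []
    h, w = len(image), len(image[0])
    for r in range(h):
        for c in range(w):
            if mask[r][c]:
                vals.append(float(image[r][c]))
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    return mean, math.sqrt(var), min(vals), max(vals)


def michelson_oracle(image, mask):
    _, _, lo, hi = intensity_oracle(image, mask)
    if hi == 0.0:
        return 0.0
    return (hi - lo) / (hi + lo)


def block_oracle(image, mask, block_size=50, min_coverage=0.5):
    """Per-block (mean intensity, Michelson) for retained blocks.

    Blocks tile the mask bounding box from its top-left corner; a block is
    retained when its in-mask pixel count reaches ``min_coverage`` of a
    full block.
    """
    h, w = len(image), len(image[0])
    rmin, rmax, cmin, cmax = h, -1, w, -1
    for r in range(h):
        for c in range(w):
            if mask[r][c]:
                rmin, rmax = min(rmin, r), max(rmax, r)
                cmin, cmax = min(cmin, c), max(cmax, c)
    blocks = []
    need = min_coverage * block_size * block_size
    br = rmin
    while br <= rmax:
        bc = cmin
        while bc <= cmax:
            vals = []
            for r in range(br, min(br + block_size, h)):
                for c in range(bc, min(bc + block_size, w)):
                    if mask[r][c]:
                        vals.append(float(image[r][c]))
            if len(vals) >= need:
                mean = sum(vals) / len(vals)
                lo, hi = min(vals), max(vals)
                mich = 0.0 if hi == 0.0 else (hi - lo) / (hi + lo)
                blocks.append((mean, mich))
            bc += block_size
        br += block_size
    return blocks


def sd(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def threshold_sweep_oracle(predicted, is_perfect):
    """Best (threshold, accuracy) by exhaustive loop; ties to the higher
    threshold."""
    cands = sorted(set(list(predicted) + [0.0, 1.0]))
    best_t, best_acc = None, -1.0
    for t in cands:
        correct = sum(
            1 for p, perf in zip(predicted, is_perfect) if (p >= t) == perf
        )
        acc = correct / len(predicted)
        if acc >= best_acc:
            best_t, best_acc = t, acc
    return best_t, best_acc
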