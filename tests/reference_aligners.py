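"""Textbook Smith-Waterman and Gotoh aligners, written independently of the
engine (plain per-column scoring, no contiguity tracking), used as the
bit-compatibility reference for linear contiguity functions."""

NEG = float("-inf")


def sw_linear(target, query, match=1, mismatch=8, gap=20, local=True):
    """Classic Smith-Waterman with per-column (linear) gap cost.

    Local mode floors at 0 and returns the matrix maximum; global mode
    initializes boundaries with cumulative gap costs and returns the
    terminal cell.
    """
    n, m = len(target), len(query)
    prev = [0] * (m + 1) if local else [-gap * j for j in range(m + 1)]
    best = 0 if local else NEG
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        cur[0] = 0 if local else -gap * i
        ti = target[i - 1]
        for j in range(1, m + 1):
            s = match if (ti == query[j - 1] and ti != "N") else -mismatch
            v = prev[j - 1] + s
            h = cur[j - 1] - gap
            if h > v:
                v = h
            u = prev[j] - gap
            if u > v:
                v = u
            if local and v < 0:
                v = 0
            cur[j] = v
            if local and v > best:
                best = v
        prev = cur
    return best if local else prev[m]


def gotoh_affine(target, query, match=1, mismatch=8, gap_open=200,
                 gap_extend=20, local=True):
    """Three-state gap-affine alignment (Gotoh); a k-gap costs
    gap_open + k * gap_extend."""
    n, m = len(target), len(query)
    oc = gap_open + gap_extend
    if local:
        h_prev = [0] * (m + 1)
        e_prev = [NEG] * (m + 1)
    else:
        h_prev = [0] + [-(gap_open + j * gap_extend) for j in range(1, m + 1)]
        e_prev = [NEG] + [-(gap_open + j * gap_extend) for j in range(1, m + 1)]
    f_prev = [NEG] * (m + 1)
    best = 0 if local else NEG
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        e_cur = [NEG] * (m + 1)
        f_cur = [NEG] * (m + 1)
        if not local:
            h_cur[0] = -(gap_open + i * gap_extend)
            f_cur[0] = h_cur[0]
        ti = target[i - 1]
        for j in range(1, m + 1):
            e = max(
                e_cur[j - 1] - gap_extend if e_cur[j - 1] > NEG else NEG,
                h_cur[j - 1] - oc if h_cur[j - 1] > NEG else NEG,
            )
            f = max(
                f_prev[j] - gap_extend if f_prev[j] > NEG else NEG,
                h_prev[j] - oc if h_prev[j] > NEG else NEG,
            )
            s = match if (ti == query[j - 1] and ti != "N") else -mismatch
            d = h_prev[j - 1] + s if h_prev[j - 1] > NEG else NEG
            v = max(d, e, f)
            if local and v < 0:
                v = 0
            h_cur[j] = v
            e_cur[j] = e
            f_cur[j] = f
            if local and v > best:
                best = v
        h_prev, e_prev, f_prev = h_cur, e_cur, f_cur
    return best if local else h_prev[m]
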