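"""Independent brute-force oracles used to validate the fast detectors.

These deliberately re-derive every definition from first principles —
full-diagonal enumeration for repeats, explicit pathway permutation for
NG86 — and share no code with the implementations they check.
"""

import itertools

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def comp(s):
    return s.translate(_COMP)


def rc(s):
    return s.translate(_COMP)[::-1]


def oracle_ssrs(seq, thresholds):
    """All maximal perfect tandem repeats of a linear sequence."""
    n = len(seq)
    found = set()
    for u, thr in thresholds.items():
        for start in range(n - u):
            # maximal on the left: no period-u extension before `start`
            if start > 0 and seq[start - 1] == seq[start + u - 1]:
                continue
            j = start + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            copies = (j - start) // u
            if copies < thr:
                continue
            motif = seq[start:start + u]
            if any(u % d == 0 and motif == motif[:d] * (u // d)
                   for d in range(1, u)):
                continue  # non-primitive motif: reported at its true period
            found.add((start, motif, copies))
    return found


def _diagonal_pairs(seq, z, e, rtype, h, min_len, min_identity):
    n = len(seq)
    lo, hi = max(0, -e), min(n, n - e)
    if hi - lo < min_len:
        return set()
    a = np.frombuffer(seq.encode(), dtype=np.uint8)[lo:hi]
    b = np.frombuffer(z.encode(), dtype=np.uint8)[lo + e:hi + e]
    mis = (np.flatnonzero(a != b) + lo).tolist()
    bounds = [lo - 1] + mis + [hi]
    if len(mis) <= h:
        windows = {(lo, hi)}
    else:
        windows = {(bounds[j] + 1, bounds[j + h + 1])
                   for j in range(len(mis) - h + 1)}
    out = set()
    for wa, wb in windows:
        length = wb - wa
        if length < min_len:
            continue
        mm = sum(1 for p in mis if wa <= p < wb)
        if (length - mm) / length < min_identity:
            continue
        if rtype in ("forward", "complement"):
            p1, p2 = wa, wa + e
        else:
            p1, p2 = wa, n - wb - e
        if p2 < p1:
            p1, p2 = p2, p1
        out.add((rtype, p1, p2, length, mm))
    return out


def oracle_dispersed(seq, min_len=30, max_hamming=3, min_identity=0.90):
    """All maximal <=k-mismatch repeat pairs of the four orientations,
    by exhaustive enumeration of every (anti)diagonal of a linear sequence."""
    n = len(seq)
    out = set()
    for rtype, z in (("forward", seq), ("complement", comp(seq)),
                     ("reverse", seq[::-1]), ("palindromic", rc(seq))):
        lo_e = 1 if rtype in ("forward", "complement") else -(n - 1)
        for e in range(lo_e, n):
            out |= _diagonal_pairs(seq, z, e, rtype, max_hamming,
                                   min_len, min_identity)
    return out


def oracle_inverted_repeat(seq, min_len, max_mismatch):
    """Longest inverted-repeat pair with <= max_mismatch mismatches.

    Exhaustive anti-diagonal scan of a linear sequence (the genome is
    assumed already rotated so neither IR copy wraps). Returns
    (start1, start2, length, mismatches) with disjoint copies.
    """
    n = len(seq)
    z = rc(seq)  # z[q] = comp(seq[n-1-q]); pair condition seq[x]==z[x+e]
    best = None
    a_all = np.frombuffer(seq.encode(), dtype=np.uint8)
    b_all = np.frombuffer(z.encode(), dtype=np.uint8)
    for e in range(-(n - 1), n):
        lo, hi = max(0, -e), min(n, n - e)
        if hi - lo < min_len:
            continue
        mis = (np.flatnonzero(a_all[lo:hi] != b_all[lo + e:hi + e]) + lo).tolist()
        bounds = [lo - 1] + mis + [hi]
        if len(mis) <= max_mismatch:
            windows = {(lo, hi)}
        else:
            windows = {(bounds[j] + 1, bounds[j + max_mismatch + 1])
                       for j in range(len(mis) - max_mismatch + 1)}
        for wa, wb in windows:
            length = wb - wa
            if length < min_len:
                continue
            p1, p2 = wa, n - wb - e
            if p2 < p1:
                p1, p2 = p2, p1
            if p1 + length > p2:  # overlapping copies
                continue
            mm = sum(1 for p in mis if wa <= p < wb)
            if mm > max_mismatch:
                continue
            cand = (length, -mm, p1, p2)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    length, neg_mm, p1, p2 = best
    return (p1, p2, length, -neg_mm)


def oracle_ng86_pair(c1, c2, fwd, stops):
    """(syn, nonsyn) differences between two codons by explicit pathway
    enumeration; stop-passing pathways excluded, with the all-blocked
    fallback counting stop steps as nonsynonymous."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(skip_stops):
        results = []
        for perm in itertools.permutations(diffs):
            cur = c1
            sd = nd = 0
            ok = True
            for i in perm:
                nxt = cur[:i] + c2[i] + cur[i + 1:]
                if skip_stops and nxt in stops:
                    ok = False
                    break
                if (nxt not in stops and cur not in stops
                        and fwd.get(nxt) == fwd.get(cur)):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    results = walk(True) or walk(False)
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))
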