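"""Independent brute-force NG86 oracle, written from the 1986 counting method
description with a hard-coded genetic code (no shared code with the package).

Conventions (matching the published method): per-position synonymous site
fraction = synonymous changes / viable changes, with nonsense (stop-creating)
mutations disregarded on both sides so each position contributes one site;
multi-position codon differences averaged over all
minimal mutational pathways, pathways through stop codons excluded (all
pathways used if every one is blocked); Jukes–Cantor correction applied to
both proportions.
"""

import itertools
import math

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE = {}
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]


def oracle_syn_sites(codon):
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = viable = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[alt] == "*":
                continue
            viable += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if viable:
            total += syn / viable
    return total


def oracle_path_counts(c1, c2):
    positions = [k for k in range(3) if c1[k] != c2[k]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in itertools.permutations(positions):
        cur = c1
        s = n = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                hit_stop = True
                n += 1
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        (blocked if hit_stop else clean).append((s, n))
    use = clean if clean else blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def oracle_ng86(seq1, seq2):
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3], seq2[k:k + 3]
        s_avg = (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2.0
        S += s_avg
        N += 3.0 - s_avg
        sd, nd = oracle_path_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return {"s_sites": S, "n_sites": N, "sd": Sd, "nd": Nd,
            "ps": ps, "pn": pn, "ks": jc(ps), "ka": jc(pn)}
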