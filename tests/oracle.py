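"""Naive position-by-position in silico PCR oracle.

Deliberately dumb pure-Python reimplementation of the matching rules,
written from the rules themselves and kept independent of the package's
vectorised scanner so the two can be compared on random instances.
"""

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
        "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
        "S": "S", "W": "W", "N": "N"}


def rc(seq):
    return "".join(COMP[c] for c in reversed(seq))


def naive_sites(primer, template, max_mm, anchor):
    """(strand, start, mismatches) for every admissible window.

    Plus strand: primer text vs template text, 3' anchor = last bases of
    the window. Minus strand: reverse complement of the primer vs the
    template text, anchor = first bases of the window.
    """
    out = []
    m = len(primer)
    for strand, query in (("+", primer), ("-", rc(primer))):
        for off in range(len(template) - m + 1):
            window = template[off:off + m]
            mism = [i for i in range(m)
                    if not (IUPAC[query[i]] & IUPAC[window[i]])]
            if len(mism) > max_mm:
                continue
            if anchor > 0:
                if strand == "+":
                    anchor_positions = set(range(m - anchor, m))
                else:
                    anchor_positions = set(range(anchor))
                if any(i in anchor_positions for i in mism):
                    continue
            out.append((strand, off, len(mism)))
    return sorted(out)


def naive_products(fwd, rev, template, max_mm, anchor, product_min, product_max):
    """Sorted product sizes of every inward-facing F/R pairing."""
    f_sites = naive_sites(fwd, template, max_mm, anchor)
    r_sites = naive_sites(rev, template, max_mm, anchor)
    floor = max(product_min, len(fwd) + len(rev))
    products = []
    for upstream, downstream, len_down in (
        ([s for s in f_sites if s[0] == "+"],
         [s for s in r_sites if s[0] == "-"], len(rev)),
        ([s for s in r_sites if s[0] == "+"],
         [s for s in f_sites if s[0] == "-"], len(fwd)),
    ):
        for _, a, _ in upstream:
            for _, b, _ in downstream:
                product = b + len_down - a
                if floor <= product <= product_max:
                    products.append(product)
    return sorted(products)
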