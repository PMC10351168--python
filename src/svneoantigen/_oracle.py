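"""Naive truth oracle for synthetic fixtures.

A deliberately independent re-derivation of the whole prediction method
using nothing but string operations on the *written* FASTA/GTF/VCF files:
its own FASTA/GTF/VCF line parsers, a hard-coded codon table, manual
splicing by slicing, single-frame translation, exhaustive window
enumeration, and substring self-filtering.  It never imports the pipeline's
types, so agreement between the two is a genuine cross-check rather than a
tautology.

Everything here is plain dicts and tuples; coordinates are kept 1-based as
in the files except where noted.
"""

from __future__ import annotations

import re

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON = {a + b + c: _AA[16 * i + 4 * j + k]
         for i, a in enumerate(_BASES)
         for j, b in enumerate(_BASES)
         for k, c in enumerate(_BASES)}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def load_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif line and name is not None:
                seqs[name].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def load_gtf(path: str) -> dict[str, dict]:
    """transcript_id -> {chrom, strand, gene, exons, cds} (1-based inclusive,
    ascending genomic order)."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] not in ("exon", "CDS"):
                continue
            attrs = dict(re.findall(r'(\w+) "([^"]*)"', f[8]))
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            rec = out.setdefault(tid, {"chrom": f[0], "strand": f[6],
                                       "gene": gid, "exons": [], "cds": []})
            key = "exons" if f[2] == "exon" else "cds"
            rec[key].append((int(f[3]), int(f[4])))
    for rec in out.values():
        rec["exons"].sort()
        rec["cds"].sort()
    return out


def load_vcf_pairs(path: str) -> list[tuple]:
    """(id, (chrom, pos, orient), (chrom, pos, orient)) per junction, with
    BND mates deduplicated and symbolic alleles expanded."""
    pairs: dict[tuple, tuple] = {}
    bnd = re.compile(r"^([ACGTNacgtn]*)([\[\]])([^:\[\]]+):(\d+)([\[\]])([ACGTNacgtn]*)$")
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, pos, rid, alt = f[0], int(f[1]), f[2], f[4]
            info = f[7].strip()
            if alt.startswith("<"):
                kind = alt.strip("<>")
                end = int(re.search(r"END=(\d+)", info).group(1))
                if kind == "DEL":
                    ends = [((chrom, pos, "L"), (chrom, end, "R"))]
                    ids = [rid]
                elif kind == "DUP":
                    ends = [((chrom, pos, "R"), (chrom, end, "L"))]
                    ids = [rid]
                elif kind == "INV":
                    ends = [((chrom, pos, "L"), (chrom, end, "L")),
                            ((chrom, pos, "R"), (chrom, end, "R"))]
                    ids = [rid + "_h2h", rid + "_t2t"]
                else:
                    continue
                for i, e in zip(ids, ends):
                    pairs[tuple(sorted(e))] = (i, *e)
            else:
                m = bnd.match(alt)
                if not m:
                    continue
                prefix, br = m.group(1), m.group(2)
                local = (chrom, pos, "L" if prefix else "R")
                mate = (m.group(3), int(m.group(4)), "R" if br == "[" else "L")
                pid = rid
                mm = re.search(r"MATEID=([^;\s]+)", info)
                if mm:  # mates are written as <pair>_1 / <pair>_2
                    pid = re.sub(r"_[12]$", "", min(rid, mm.group(1)))
                key = tuple(sorted((local, mate)))
                if key not in pairs:
                    pairs[key] = (pid, local, mate)
    return list(pairs.values())


# ---------------------------------------------------------------------------
# transcript geometry on the parsed GTF


def _tx_structure(rec: dict, genome: dict[str, str]) -> dict:
    """Spliced sequence plus utr5/cds lengths and transcription-order exons
    as (start, end) 1-based inclusive."""
    exons = rec["exons"] if rec["strand"] == "+" else rec["exons"][::-1]
    chrom_seq = genome[rec["chrom"]]
    parts = []
    for s, e in exons:
        seg = chrom_seq[s - 1:e]
        parts.append(seg if rec["strand"] == "+" else rc(seg))
    seq = "".join(parts)
    cds_len = sum(e - s + 1 for s, e in rec["cds"])
    utr5 = 0
    if cds_len:
        if rec["strand"] == "+":
            cds_start_g = min(s for s, _ in rec["cds"])
            utr5 = _tx_offset(exons, "+", cds_start_g)
        else:
            cds_start_g = max(e for _, e in rec["cds"])
            utr5 = _tx_offset(exons, "-", cds_start_g)
    return {"seq": seq, "exons": exons, "utr5": utr5, "cds_len": cds_len,
            "strand": rec["strand"], "chrom": rec["chrom"], "gene": rec["gene"]}


def _tx_offset(exons: list, strand: str, gpos: int) -> int | None:
    """0-based transcript offset of a 1-based exonic genomic position."""
    off = 0
    for s, e in exons:
        if s <= gpos <= e:
            return off + (gpos - s if strand == "+" else e - gpos)
        off += e - s + 1
    return None


def _intron_index(exons: list, strand: str, gpos: int) -> int | None:
    for i in range(len(exons) - 1):
        a, b = exons[i], exons[i + 1]
        lo, hi = (a[1] + 1, b[0] - 1) if strand == "+" else (b[1] + 1, a[0] - 1)
        if lo <= gpos <= hi:
            return i
    return None


def _select(gtf: dict, genome: dict) -> dict[str, dict]:
    """gene -> structure of the longest-CDS isoform (ties: smallest tid)."""
    best: dict[str, tuple] = {}
    for tid in sorted(gtf):
        st = _tx_structure(gtf[tid], genome)
        if st["cds_len"] == 0:
            continue
        g = st["gene"]
        if g not in best or st["cds_len"] > best[g][0]:
            best[g] = (st["cds_len"], st)
    return {g: v[1] for g, v in best.items()}


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON.get(seq[i:i + 3], "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def proteome(gtf: dict, genome: dict) -> dict[str, str]:
    out = {}
    for g, st in _select(gtf, genome).items():
        out[g] = translate(st["seq"][st["utr5"]:st["utr5"] + st["cds_len"]])
    return out


# ---------------------------------------------------------------------------
# full re-derivation of one junction


def evaluate(pair: tuple, gtf: dict, genome: dict) -> dict:
    """Expected pipeline outcome for one breakend pair.

    Returns feasible / reject reason, frameshift flag, neo-protein sequence,
    mutated span, termination, and the non-self 8-11-mer peptide set.
    """
    _, end1, end2 = pair
    selected = _select(gtf, genome)
    prot = proteome(gtf, genome)

    def locate(end):
        chrom, pos, orient = end
        hits = []
        for g, st in selected.items():
            if st["chrom"] != chrom:
                continue
            lo = min(s for s, _ in st["exons"])
            hi = max(e for _, e in st["exons"])
            if lo <= pos <= hi:
                hits.append((-st["cds_len"], g))
        if not hits:
            return None
        return min(hits)[1]

    g1, g2 = locate(end1), locate(end2)
    if g1 is None or g2 is None:
        return {"feasible": False, "reject": "INTERGENIC"}

    def donor_ok(end, gene):
        st = selected[gene]
        want = "L" if st["strand"] == "+" else "R"
        return end[2] == want

    def acceptor_ok(end, gene):
        st = selected[gene]
        want = "R" if st["strand"] == "+" else "L"
        return end[2] == want

    def in_utr3(end, gene):
        st = selected[gene]
        off = _tx_offset(st["exons"], st["strand"], end[1])
        if off is None:  # intronic: use exonic length 5' of the intron
            i = _intron_index(st["exons"], st["strand"], end[1])
            off = sum(e - s + 1 for s, e in st["exons"][:i + 1])
        return off >= st["utr5"] + st["cds_len"]

    assignments = [(e_d, g_d, e_a, g_a)
                   for (e_d, g_d), (e_a, g_a) in
                   [((end1, g1), (end2, g2)), ((end2, g2), (end1, g1))]
                   if donor_ok(e_d, g_d) and acceptor_ok(e_a, g_a)]
    if not assignments:
        return {"feasible": False, "reject": "ORIENTATION"}
    coding = [a for a in assignments if not in_utr3(a[0], a[1])]
    if not coding:
        return {"feasible": False, "reject": "NO_CODING_EFFECT"}
    e_d, g_d, e_a, g_a = coding[0]
    d_st, a_st = selected[g_d], selected[g_a]

    # donor prefix length in transcript nt
    off = _tx_offset(d_st["exons"], d_st["strand"], e_d[1])
    if off is not None:
        prefix_len = off + 1
    else:
        i = _intron_index(d_st["exons"], d_st["strand"], e_d[1])
        prefix_len = sum(e - s + 1 for s, e in d_st["exons"][:i + 1])
    # acceptor suffix start
    aoff = _tx_offset(a_st["exons"], a_st["strand"], e_a[1])
    if aoff is None:
        i = _intron_index(a_st["exons"], a_st["strand"], e_a[1])
        aoff = sum(e - s + 1 for s, e in a_st["exons"][:i + 1])

    mrna = d_st["seq"][:prefix_len] + a_st["seq"][aoff:]
    if len(mrna) == prefix_len:
        return {"feasible": False, "reject": "NO_UTR_STRUCTURE"}
    if prefix_len < d_st["utr5"] + 3:
        return {"feasible": False, "reject": "NO_UTR_STRUCTURE"}

    cds_start = d_st["utr5"]
    protein = translate(mrna[cds_start:])
    stopped = "*" in [CODON.get(mrna[cds_start:][i:i + 3], "X")
                      for i in range(0, len(mrna[cds_start:]) - 2, 3)]
    termination = "STOP" if stopped else "READ_THROUGH"

    # frameshift: first acceptor coding base must keep its native phase
    if a_st["cds_len"] and aoff < a_st["utr5"] + a_st["cds_len"]:
        if aoff < a_st["utr5"]:
            native, gap = 0, a_st["utr5"] - aoff
        else:
            native, gap = (aoff - a_st["utr5"]) % 3, 0
        frameshift = (prefix_len + gap - cds_start) % 3 != native
    else:
        frameshift = True

    wt = prot[g_d]
    p = 0
    while p < min(len(protein), len(wt)) and protein[p] == wt[p]:
        p += 1
    if frameshift or g_d != g_a or termination == "READ_THROUGH":
        span = (p, len(protein)) if p < len(protein) else (p, p)
    else:
        s = 0
        while s < min(len(protein), len(wt)) and protein[-1 - s] == wt[-1 - s]:
            s += 1
        s = min(s, len(protein) - p, len(wt) - p)
        span = (p, max(p, len(protein) - s))

    peptides: set[str] = set()
    lo, hi = span
    if hi > lo:
        haystack = "|".join(prot.values())
        for k in range(8, 12):
            for i in range(len(protein) - k + 1):
                if i + k > lo and i < hi:
                    pep = protein[i:i + k]
                    if "X" not in pep and pep not in haystack:
                        peptides.add(pep)

    return {"feasible": True, "reject": None, "frameshift": frameshift,
            "protein": protein, "span": span, "termination": termination,
            "donor_gene": g_d, "acceptor_gene": g_a, "peptides": peptides}
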