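"""Reading and writing genotype matrices in Genepop format.

The dialect written here uses 4-digit diploid genotypes (two 2-digit
allele codes, here raw repeat counts), one locus name per line, and POP
delimiters between subpopulations — the layout accepted by Genepop
itself and by the common R wrappers.
"""

from __future__ import annotations

import numpy as np

from .sumstats import SampleMatrix


def write_genepop(sample: SampleMatrix, path, title: str = "ballmoss export",
                  locus_names: list[str] | None = None) -> None:
    L = sample.n_loci
    if locus_names is None:
        locus_names = [f"L{l + 1}" for l in range(L)]
    if len(locus_names) != L:
        raise ValueError("locus_names length mismatch")
    if sample.genotypes.size and sample.genotypes.max() > 99:
        raise ValueError("allele codes exceed 2 digits")
    with open(path, "w") as fh:
        fh.write(title.strip() + "\n")
        for name in locus_names:
            fh.write(name + "\n")
        for p in sample.pops():
            fh.write("POP\n")
            rows = np.flatnonzero(sample.subpop == p)
            for k, i in enumerate(rows):
                g = sample.genotypes[i]
                codes = " ".join(f"{int(a):02d}{int(b):02d}" for a, b in g)
                fh.write(f"pop{p}_{k} , {codes}\n")


def read_genepop(path) -> SampleMatrix:
    """Parse a Genepop file into a SampleMatrix (no coordinates).

    Handles 2- and 3-digit allele codes and both locus-per-line and
    comma-separated locus headers. Missing genotypes (code 0) are not
    supported — simulated/complete data only.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    locus_names: list[str] = []
    i = 1  # skip title
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    genotypes, subpop = [], []
    pop = -1
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            pop += 1
            continue
        name, _, codes = ln.partition(",")
        fields = codes.split()
        if len(fields) != len(locus_names):
            raise ValueError(f"bad genotype line: {ln!r}")
        row = []
        for c in fields:
            if len(c) % 2:
                raise ValueError(f"odd-width genotype code {c!r}")
            w = len(c) // 2
            a, b = int(c[:w]), int(c[w:])
            if a == 0 or b == 0:
                raise ValueError("missing data not supported")
            row.append(sorted((a, b)))
        genotypes.append(row)
        subpop.append(pop)
    return SampleMatrix(
        np.array(genotypes, dtype=np.int16),
        np.array(subpop, dtype=np.int64),
    )
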