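"""Chromosome-arm label sets used throughout the package.

A diploid human genome carries 92 telomere sites (22 autosomal pairs x 4
arms + 4 sex-chromosome arms).  After collapsing the two haplotypes, up to
48 distinct arm labels remain per person.  The short arms of the
acrocentric chromosomes (13p, 14p, 15p, 21p, 22p) share pseudo-homologous
sequence and cannot be assigned a telomere unambiguously; together with
the sex-chromosome arms they are excluded from association analyses,
leaving 39 autosomal arms.
"""

from __future__ import annotations

#: All 48 collapsed arm labels (22 autosomes x {p,q} + Xp, Xq, Yp, Yq).
ARM_LABELS: tuple[str, ...] = tuple(
    f"{c}{a}" for c in range(1, 23) for a in ("p", "q")
) + ("Xp", "Xq", "Yp", "Yq")

#: Acrocentric short arms with pseudo-homologous subtelomeres.
ACROCENTRIC_P: frozenset[str] = frozenset({"13p", "14p", "15p", "21p", "22p"})

#: Sex-chromosome arms (pseudo-autosomal recombination).
SEX_ARMS: frozenset[str] = frozenset({"Xp", "Xq", "Yp", "Yq"})

#: The 39 autosomal arms retained for association analyses.
ANALYSIS_ARMS: tuple[str, ...] = tuple(
    a for a in ARM_LABELS if a not in ACROCENTRIC_P and a not in SEX_ARMS
)

#: Number of per-haplotype telomere sites in a diploid genome.
N_DIPLOID_SITES: int = 92

assert len(ARM_LABELS) == 48
assert len(ANALYSIS_ARMS) == 39
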