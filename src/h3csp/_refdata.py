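"""Embedded reference data: the Xenopus laevis histone H3 sequence and a
random-coil chemical-shift table used by the synthetic generator.

The random-coil values are generic backbone baselines near the standard
literature random-coil shifts (Wishart-style tables, ppm).  Only shift
*differences* between conditions matter anywhere downstream, so the absolute
baselines are deliberately approximate; they exist to make synthetic tables
look like real depositions (residue-type spread, helix offsets).
"""

from __future__ import annotations

# Canonical X. laevis histone H3, 135 residues, numbering 1-135 (matches the
# H3 chains of nucleosome crystal structures such as 1KX5).
H3_SEQUENCE = (
    "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHR"  # 1-40
    "YRPGTVALREIRRYQKSTELLIRKLPFQRLVREIAQDFKT"  # 41-80
    "DLRFQSSAVMALQEASEAYLVGLFEDTNLCAIHAKRVTIM"  # 81-120
    "PKDIQLARRIRGERA"                            # 121-135
)

H3_OFFSET = 1

# Structured core detectable in dipolar-based spectra.
H3_CORE_RANGE = (44, 132)

# The four core-domain helices (approximate 1KX5 boundaries):
# alphaN, alpha1, alpha2, alpha3.
H3_HELICES = [(45, 56), (64, 77), (86, 113), (121, 130)]

# Segments invisible in both J- and dipolar-based spectra (tail-core boundary
# and the L1 loop).
H3_UNDETECTABLE = [(35, 43), (78, 81)]

# Random-coil backbone shifts (ppm) per residue type: H(N), N, CA, CB, C(O).
# Glycine has no CB; proline has no amide H or (in this pipeline's model) N.
RANDOM_COIL: dict[str, dict[str, float]] = {
    "A": {"H": 8.24, "N": 123.8, "CA": 52.5, "CB": 19.1, "C": 177.8},
    "R": {"H": 8.23, "N": 120.5, "CA": 56.0, "CB": 30.9, "C": 176.3},
    "N": {"H": 8.40, "N": 118.7, "CA": 53.1, "CB": 38.9, "C": 175.2},
    "D": {"H": 8.34, "N": 120.4, "CA": 54.2, "CB": 41.1, "C": 176.3},
    "C": {"H": 8.32, "N": 118.8, "CA": 58.2, "CB": 28.0, "C": 174.6},
    "Q": {"H": 8.32, "N": 119.8, "CA": 55.7, "CB": 29.4, "C": 176.0},
    "E": {"H": 8.42, "N": 120.2, "CA": 56.6, "CB": 29.9, "C": 176.6},
    "G": {"H": 8.33, "N": 108.8, "CA": 45.1, "C": 174.9},
    "H": {"H": 8.42, "N": 118.2, "CA": 55.0, "CB": 29.0, "C": 174.1},
    "I": {"H": 8.00, "N": 119.9, "CA": 61.1, "CB": 38.8, "C": 176.4},
    "L": {"H": 8.16, "N": 121.8, "CA": 55.1, "CB": 42.4, "C": 177.6},
    "K": {"H": 8.29, "N": 120.4, "CA": 56.2, "CB": 33.1, "C": 176.6},
    "M": {"H": 8.28, "N": 119.6, "CA": 55.4, "CB": 32.9, "C": 176.3},
    "F": {"H": 8.30, "N": 120.3, "CA": 57.7, "CB": 39.6, "C": 175.8},
    "P": {"CA": 63.3, "CB": 32.1, "C": 177.3},
    "S": {"H": 8.31, "N": 115.7, "CA": 58.3, "CB": 63.8, "C": 174.6},
    "T": {"H": 8.15, "N": 113.6, "CA": 61.8, "CB": 69.8, "C": 174.7},
    "W": {"H": 8.25, "N": 121.3, "CA": 57.5, "CB": 29.6, "C": 176.1},
    "Y": {"H": 8.12, "N": 120.3, "CA": 57.9, "CB": 38.8, "C": 175.9},
    "V": {"H": 8.03, "N": 119.2, "CA": 62.2, "CB": 32.9, "C": 176.3},
}

# Secondary-structure offsets added inside helical segments (ppm).
HELIX_OFFSETS: dict[str, float] = {
    "CA": 2.8,
    "C": 1.8,
    "H": -0.25,
    "N": -1.5,
    "CB": -0.5,
}
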