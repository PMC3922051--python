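"""Primer, probe and barcode constants of the 18S V1-V3 amplicon design.

The amplicons target the hypervariable V1-V3 region of the eukaryotic 18S
rRNA gene, amplified with the universal forward primer 1A and reverse primer
564R.  Two conserved eukaryotic probes (Euk381, Euk422) fall between the
primer sites; genuine 18S reads carry at least one of them, which is the
basis of the false-amplicon screen in :mod:`brine18s.read_qc`.
"""

# Universal eukaryotic 18S primers (5'->3').
FORWARD_PRIMER_1A = "AACCTGGTTGATCCTGCCAG"
REVERSE_PRIMER_564R = "GGCACCAGACTTGCCCTC"

# Internal 18S probes located between the primer sites.
PROBE_EUK381 = "TCCGGAGAGGGAGCC"
PROBE_EUK422 = "GGCAGCAGGCACGAA"

# 8-nt sample barcodes of the seven brine-pool / cold-seep libraries:
# microbial mat (Mat), bottom water (NDW), brine-seawater interface (DBI),
# bottom sediments (DS3, DS6) and brine sediments (BS8, BS9).
SAMPLE_BARCODES = {
    "Mat": "CGGATTGC",
    "NDW": "ATGCAGTC",
    "DBI": "ATATTCGC",
    "DS3": "TTATCCGC",
    "DS6": "TATCGTCC",
    "BS8": "ACCACAAC",
    "BS9": "TCTGCGTT",
}

DNA_ALPHABET = "ACGT"
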