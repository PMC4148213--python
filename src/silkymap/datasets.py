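"""Published observations for the chicken silky-feather (hookless, h) locus.

These are the reported inputs of the silky-feather mapping study on chicken
chromosome 3 (galGal3 assembly coordinates): the F2 segregation counts, the
two-point linkage marker panel, the candidate-region coordinates produced by
each narrowing step, the breed-panel genotype counts at the candidate
promoter SNP (PDSS2 -103C>G), and the coordinate anchors tying the genomic
position of that SNP to CDS-relative numbering.  They serve as worked-example
inputs; no genotype-level data are included.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .intervals import GenomicInterval
from .markers import MarkerMap

#: F2 intercross segregation: wild-type vs silky-feather among 229 F2 birds.
F2_SEGREGATION = {"n_dominant": 162, "n_recessive": 67}

#: Candidate regions produced by successive mapping steps (1-based inclusive).
REGIONS: dict[str, GenomicInterval] = {
    # 380 kb interval from refined linkage mapping in the F2 intercross
    "linkage_f2": GenomicInterval("3", 70_201_106, 70_581_126),
    # ~589 kb interval from linkage in an independent backcross population
    "linkage_backcross": GenomicInterval("3", 70_399_176, 70_988_264),
    # proximal 57.4 kb case-shared homozygous block (later excluded)
    "proximal_block": GenomicInterval("3", 70_384_172, 70_441_580),
    # distal 56.7 kb case-shared homozygous block (survives control exclusion)
    "distal_block": GenomicInterval("3", 70_447_648, 70_504_365),
    # candidate region after het-boundary narrowing in the 12-breed panel
    "narrowed_candidate": GenomicInterval("3", 70_460_739, 70_504_365),
    # 18.9 kb minimal case-exclusive haplotype from re-sequencing
    "resequencing_haplotype": GenomicInterval("3", 70_468_129, 70_487_067),
    # 21.7 kb fixed haplotype from the 15-bird pooled whole-genome scan
    "pool_haplotype": GenomicInterval("3", 70_467_293, 70_489_020),
}

#: Boundary facts used by the het-exclusive narrowing convention: the
#: proximal IBD boundary marker and the candidate region it implies.
NARROWING = {
    "boundary_marker_bp": 70_460_738,
    "candidate_start_bp": 70_460_739,
    "candidate_end_bp": 70_504_365,
}

#: CDS-relative coordinate anchors for the candidate promoter SNP and the
#: most common transcription start site (A of ATG = +1, no position 0).
PROMOTER_SNP = {"position_bp": 70_486_623, "offset": -103}
COMMON_TSS_BP = 70_486_636

#: Breed-panel genotype counts at the candidate SNP (G = silky allele):
#: (population, phenotype class, n G/G, n G/C, n C/C).
ASSOCIATION_PANEL = [
    ("Jinyang Silky", "case", 23, 0, 0),
    ("Kuaida Silky", "case", 41, 0, 0),
    ("Lanping Silky", "case", 16, 0, 0),
    ("Silkie", "case", 257, 0, 0),
    ("CAURP F1", "obligate_het", 0, 27, 0),
    ("Silkie crossbred", "obligate_het", 0, 13, 0),
    ("Aijiao Yellow", "control", 0, 0, 10),
    ("Anak", "control", 0, 0, 10),
    ("Anyi Gray", "control", 0, 0, 10),
    ("Baier Yellow", "control", 0, 0, 10),
    ("Beijing You", "control", 0, 0, 20),
    ("Bian", "control", 0, 0, 10),
    ("Chahua", "control", 0, 0, 10),
    ("Chongren Partridge", "control", 0, 0, 10),
    ("Dagu", "control", 0, 0, 10),
    ("Dongxiang Blue-Eggshell", "control", 0, 0, 10),
    ("Gushi", "control", 0, 0, 10),
    ("Henan Game", "control", 0, 0, 10),
    ("Huiyang Bearded", "control", 0, 0, 20),
    ("Jinhu Black-Bone", "control", 0, 0, 10),
    ("Langshan", "control", 0, 0, 10),
    ("Luyuan", "control", 0, 0, 10),
    ("Qingyuan Partridge", "control", 0, 0, 10),
    ("Red Jungle Fowl", "control", 0, 0, 36),
    ("Shiqiza", "control", 0, 0, 10),
    ("Shouguang", "control", 0, 0, 10),
    ("Tibetan", "control", 0, 0, 10),
    ("Wenchang", "control", 0, 0, 10),
    ("White Leghorn", "control", 0, 0, 24),
    ("White Rock", "control", 0, 0, 21),
    ("Xianju", "control", 0, 0, 10),
    ("Xiaoshan", "control", 0, 0, 10),
    ("Youxi Partridge", "control", 0, 0, 10),
]


def linkage_marker_table() -> pd.DataFrame:
    """Two-point linkage scan marker panel on GGA3 with reported theta/LOD."""
    ref = resources.files("silkymap") / "data" / "gga3_silky_linkage_markers.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def linkage_marker_map() -> MarkerMap:
    df = linkage_marker_table()
    return MarkerMap(df[["marker", "chrom", "position_bp"]].copy())


def association_panel_frame() -> pd.DataFrame:
    return pd.DataFrame(
        ASSOCIATION_PANEL,
        columns=["population", "phenotype", "hom_alt", "het", "hom_ref"],
    )
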