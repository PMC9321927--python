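"""coldlocus: comparative gene-locus analysis for cold-adapted teleost genes.

A reusable pipeline for the comparative characterisation of a gene locus
across a focal (cold-adapted) clade and temperate relatives: gene-model I/O
and intron extraction, nucleotide features (AT content, CpG islands,
polyadenylation signals, fixed-motif tandem scans, cross-clade intron-length
comparison), protein features (sequons, cysteine spacing, composition,
charge/pI, hydropathy TM scan), grouped-MSA screening for clade-specific
substitutions with p-distance/neighbor-joining trees, and 2^-ddCq qPCR
relative-expression analysis, plus seeded synthetic-data generators with
ground-truth plant logs.
"""

from importlib import resources

import pandas as pd

from . import locus_io, msacomp, nucfeat, protfeat, qexpr, synthgen  # noqa: F401
from .locus_io import (  # noqa: F401
    GeneModel,
    GenomicInterval,
    IntronSet,
    extract_introns,
    read_gene_model,
    spliced_sequence,
)
from .nucfeat import (  # noqa: F401
    at_content,
    compare_introns,
    detect_cgi,
    obs_exp_cpg,
    scan_motif,
    scan_pas,
)
from .protfeat import (  # noqa: F401
    composition,
    cysteine_pattern,
    hydropathy_tm_scan,
    scan_sequons,
    theoretical_pi,
    translate,
)
from .msacomp import (  # noqa: F401
    GroupedAlignment,
    convergent_sequons,
    nj_tree,
    p_distance,
    screen_specific_columns,
)
from .qexpr import ddcq, pairwise_tests  # noqa: F401

__version__ = "0.1.0"


def load_reference_intron_table() -> pd.DataFrame:
    """Published pIgR intron lengths across 15 perciform species.

    Columns: species, suborder, clade (antarctic / non_antarctic_notothenioid
    / temperate), group (focal / comparison), gene_size, i1..i7.
    """
    with resources.files("coldlocus.data").joinpath(
        "notothenioid_pigr_introns.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
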