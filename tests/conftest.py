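import numpy as np
import pandas as pd
import pytest

from bioidkit import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_table(registry):
    """A 4-class labelled corpus, 60 ids per class."""
    profile = {name: 60 for name in ["ChEMBL", "Ensembl gene", "HGNC", "Pfam"]}
    return registry.generate_dataset(profile, seed=11)


@pytest.fixture(scope="session")
def toy_cm():
    """Two-class confusion matrix with hand-checkable metrics."""
    return pd.DataFrame([[8, 2], [1, 9]], index=["a", "b"], columns=["a", "b"])


# Published per-class balanced training counts of the 39-class reference
# corpus.
PUBLISHED_BALANCED = {
    "The Consensus CDS": 60_736,
    "Conserved Domain Database": 68_390,
    "ChEMBL": 69_342,
    "EMBL": 139_545,
    "Ensembl exon": 596_934,
    "Ensembl gene": 50_146,
    "Entrez Gene Database": 63_673,
    "HAMAP": 70_444,
    "HGNC": 58_617,
    "HGNC Transcript": 162_747,
    "PANTHER": 63_418,
    "Interpro": 65_267,
    "Merops": 70_317,
    "miRBase": 69_997,
    "Protein Data Bank": 56_079,
    "Pfam": 68_572,
    "pfScan": 70_282,
    "PIRSF": 70_266,
    "PRINTS": 70_106,
    "Protein": 343_233,
    "Reactome": 69_802,
    "Refseq mrna": 51_937,
    "Refseq ncrna": 65_803,
    "Refseq peptide": 53_386,
    "Rfam": 70_534,
    "Rfam transcript": 70_113,
    "RNAcentral": 62_810,
    "ScanProsite": 70_287,
    "Structure-Function Linkage Database": 70_532,
    "SMART": 70_245,
    "SUPERFAMILY": 70_217,
    "TIGRFAMs": 70_373,
    "UCSC": 158_752,
    "UniProt Archive": 63_554,
    "Uniprot gene": 64_420,
    "Uniprot isoform": 63_104,
    "Uniprot TrEMBL": 52_020,
    "Uniprot Swiss-prot": 64_765,
    "WikiGene": 63_673,
}


@pytest.fixture(scope="session")
def published_balanced():
    return dict(PUBLISHED_BALANCED)
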