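import csv
from pathlib import Path

import pytest

from duocall.cli import simulate_bundle
from duocall.pipeline import RunConfig, run_pipeline
from duocall.reference_context import ReferenceSet
from duocall.synthetic_data import SimulationConfig, read_truth_manifest


@pytest.fixture
def tiny_ref() -> ReferenceSet:
    #              1234567890123456789012345
    return ReferenceSet({"c1": "ACGTACGTAAAAACGTACGTACGTC", "c2": "TTGCATGCATGCA"})


# Hand-entered rows of the two in-paper recurrence tables (the worked example).
TABLES23_ROWS = [
    # sample, contig, pos, ref, alt, af, gene, consequence, cadd, pop_freq
    ("PN14", "chr20", 57484420, "C", "T", "41.7%", "GNAS", "Missense variant", "34", "0"),
    ("PN13", "chr20", 57484420, "C", "T", "41.0%", "GNAS", "Missense variant", "34", "0"),
    ("PN08", "chr20", 57484420, "C", "T", "45.4%", "GNAS", "Missense variant", "34", "0"),
    ("PN01", "chr16", 31818244, "C", "G", "10.3%", "AC002519.6",
     "Downstream gene variant, rs111534922", "2.24", "0"),
    ("PN07", "chr16", 31818244, "C", "G", "16.7%", "AC002519.6",
     "Downstream gene variant, rs111534922", "2.24", "0"),
    ("PN02", "chr11", 62283636, "T", "C", "", "AHNAK", "3 prime UTR variant", "0.57", "0"),
    ("PN01", "chr11", 62289022, "T", "A", "", "AHNAK", "synonymous variant", "0.008", "0.003%"),
    ("PN06", "chr9", 112625173, "G", "T", "", "PALM2/AKAP2", "Intron variant", "1.26", "0"),
    ("PN15", "chr9", 112687347, "T", "A", "", "PALM2/AKAP2",
     "Missense variant, COSV57111433", "19.12", "0"),
]


@pytest.fixture
def tables23_tsv(tmp_path: Path) -> Path:
    path = tmp_path / "tables23.tsv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample", "chrom", "position", "ref", "alt", "allele_fraction",
             "gene", "consequence", "cadd_phred", "gnomad_freq"]
        )
        w.writerows(TABLES23_ROWS)
    return path


def simulate_and_run(cfg: SimulationConfig, outdir: Path):
    """Simulate a bundle, run the pipeline on it, return (bundle, result, truths)."""
    bundle = simulate_bundle(cfg, outdir)
    run_cfg = RunConfig.from_yaml(outdir / "run_config.yaml")
    result = run_pipeline(run_cfg)
    truths = read_truth_manifest(bundle.truth_manifest)
    return bundle, result, truths


@pytest.fixture(scope="session")
def noisefree_cohort(tmp_path_factory):
    """15-sample noise-free cohort: the strongest end-to-end oracle fixture."""
    outdir = tmp_path_factory.mktemp("noisefree")
    cfg = SimulationConfig(seed=20260905, n_samples=15, binomial_noise=False)
    return simulate_and_run(cfg, outdir)
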