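import shutil
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Small simulated genome + annotation + error-free reads (shared)."""
    from ngsflow.fixtures import make_annotation, make_genome, simulate_reads

    root = tmp_path_factory.mktemp("sim")
    genome = make_genome(1, 15_000, gc=0.5, seed=42, out=root / "genome.fasta")
    gff = make_annotation(genome, n_genes=12, seed=43,
                          out=root / "annotation.gff3")
    fastq, truth, sam = simulate_reads(
        genome, gff, n_reads=400, read_len=50, error_rate=0.0, seed=44,
        out_prefix=root / "reads")
    return {"root": root, "genome": genome, "gff": gff, "fastq": fastq,
            "truth": truth, "sam": sam}


@pytest.fixture()
def toy_step(tmp_path):
    """A cp-based 4-sample step over real input files, ready to run."""
    from ngsflow.formats import read_param, read_targets

    data = tmp_path / "data"
    data.mkdir()
    names = ["S1", "S2", "S3", "S4"]
    lines = ["FileName1\tSampleName\tFactor"]
    for i, name in enumerate(names):
        f = data / f"{name}.txt"
        f.write_text(f"payload {name}\n")
        lines.append(f"{f}\t{name}\t{'A' if i < 2 else 'B'}")
    targets_path = tmp_path / "targets.txt"
    targets_path.write_text("\n".join(lines) + "\n")
    param_path = tmp_path / "step.param"
    param_path.write_text(
        "software\t\tcp\n"
        "infile\t\t<FileName1>\n"
        "outfile\t\t<SampleName>.out\n")
    from ngsflow.sysargs import build_sysargs

    targets = read_targets(targets_path)
    param = read_param(param_path)
    step = build_sysargs(targets, param, step_name="copy",
                         outdir=str(tmp_path / "results"))
    return step, tmp_path
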