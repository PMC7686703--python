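"""Plain-text (TSV) readers and writers for the pipeline's tables.

Matrices (beta, detection p) are probes × samples with one header line;
missing values are written as ``NA``.  Floats are serialised with ``repr``
precision so a re-run with the same seed produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import ProbeExclusionLists
from .simulate import ReferenceProfiles

NA = "NA"


def _fmt(v) -> str:
    if pd.isna(v):
        return NA
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_table(df: pd.DataFrame, path, index_name: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        name = index_name or (df.index.name or "id")
        fh.write("\t".join([name] + [str(c) for c in df.columns]) + "\n")
        for idx, row in zip(df.index, df.itertuples(index=False)):
            fh.write("\t".join([str(idx)] + [_fmt(v) for v in row]) + "\n")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def read_exclusion_dir(directory) -> ProbeExclusionLists:
    """Read one-probe-per-line exclusion files named <list>.txt from a directory."""
    directory = Path(directory)
    kwargs = {}
    for name in ("non_cpg", "snp_related", "chr_y", "trimodal"):
        f = directory / f"{name}.txt"
        if f.exists():
            kwargs[name] = [ln.strip() for ln in f.read_text().splitlines() if ln.strip()]
    return ProbeExclusionLists(**kwargs)


def write_reference(refs: ReferenceProfiles, path) -> None:
    """Reference TSV: a '#compartment' header row, then cell types × probes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(["#compartment"] +
                           [refs.compartments[c] for c in refs.cell_types]) + "\n")
        fh.write("\t".join(["probe"] + list(refs.cell_types)) + "\n")
        mu = refs.mu
        for probe in mu.columns:
            fh.write("\t".join([str(probe)] + [repr(float(v)) for v in mu[probe]]) + "\n")


def read_reference(path) -> ReferenceProfiles:
    with open(path) as fh:
        comp_line = fh.readline().rstrip("\n").split("\t")
        if comp_line[0] != "#compartment":
            raise ValueError("reference file must start with a '#compartment' row")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    compartments = dict(zip(df.columns, comp_line[1:]))
    return ReferenceProfiles(mu=df.T, compartments=compartments)


def save_cohort(cohort, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.beta, outdir / "beta.tsv", index_name="probe")
    write_table(cohort.detection_p, outdir / "detection_p.tsv", index_name="probe")
    write_table(cohort.sample_sheet, outdir / "sample_sheet.tsv", index_name="sample")
    write_table(cohort.abundance, outdir / "abundance.tsv", index_name="sample")
    truth = []
    for kind, series in cohort.truth.items():
        for probe, effect in series.items():
            truth.append((probe, kind, effect))
    write_table(
        pd.DataFrame(truth, columns=["probe", "kind", "effect"]).set_index("probe"),
        outdir / "truth.tsv", index_name="probe",
    )
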