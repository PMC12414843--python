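"""Plain-TSV readers and writers for every pipeline artefact.

All tables are tab-separated with a header row; missing values are written as
"NA". Keeping every intermediate as TSV makes each stage independently
inspectable and re-runnable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .quant import RatioMatrix
from .simulate import SampleRecord, subtype_of

NA = "NA"


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label=index_label)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA])


def write_cohort(cohort: list[SampleRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "hr_status": "positive" if r.hr_status else "negative",
            "her2_status": "positive" if r.her2_status else "negative",
            "subtype": r.subtype,
            "batch_id": r.batch_id,
            "channel_id": r.channel_id,
        }
        for r in cohort
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA)


def read_cohort(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    records = []
    for row in df.itertuples(index=False):
        hr = row.hr_status == "positive"
        her2 = row.her2_status == "positive"
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                hr_status=hr,
                her2_status=her2,
                subtype=subtype_of(hr, her2),
                batch_id=None if pd.isna(row.batch_id) else int(row.batch_id),
                channel_id=None if pd.isna(row.channel_id) else int(row.channel_id),
            )
        )
    return records


def write_batch_tables(tables: dict[int, pd.DataFrame], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b, t in sorted(tables.items()):
        p = outdir / f"batch_{b:02d}.tsv"
        write_table(t, p, index_label="protein")
        paths.append(p)
    return paths


def read_batch_tables(outdir) -> dict[int, pd.DataFrame]:
    tables = {}
    for p in sorted(Path(outdir).glob("batch_*.tsv")):
        b = int(p.stem.split("_")[1])
        tables[b] = read_table(p)
    if not tables:
        raise FileNotFoundError(f"no batch_*.tsv files under {outdir}")
    return tables


def write_ratio_matrix(matrix: RatioMatrix, path) -> None:
    write_table(matrix.data, path, index_label="protein")


def read_ratio_matrix(path, cohort: list[SampleRecord]) -> RatioMatrix:
    data = read_table(path)
    batches = pd.Series({r.sample_id: r.batch_id for r in cohort})
    return RatioMatrix(data=data, batches=batches.loc[list(data.columns)])
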