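"""FPKM expression matrix with stage/replicate sample metadata."""

from __future__ import annotations

import re

import pandas as pd

from .errors import LookupError_, ValidationError

__all__ = ["ExpressionMatrix"]

_SAMPLE_RE = re.compile(r"^(?P<stage>.+)_(?P<rep>\d+)$")


class ExpressionMatrix:
    """FPKM values, samples x transcripts, with per-sample (stage, replicate).

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are transcript ids, all
        entries >= 0 (FPKM).
    sample_meta
        DataFrame indexed by sample id with columns ``stage`` and
        ``replicate``. If omitted, sample ids of the form ``<stage>_<rep>``
        are parsed.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        if values.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate transcript ids")
        if (values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be >= 0")
        if sample_meta is None:
            rows = []
            for s in values.index:
                m = _SAMPLE_RE.match(str(s))
                if m is None:
                    raise ValidationError(
                        f"cannot parse stage/replicate from sample id {s!r}; "
                        "provide sample_meta explicitly"
                    )
                rows.append((s, m["stage"], int(m["rep"])))
            sample_meta = pd.DataFrame(
                rows, columns=["sample", "stage", "replicate"]
            ).set_index("sample")
        missing = set(values.index) - set(sample_meta.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
        self.values = values
        self.sample_meta = sample_meta.loc[values.index]

    # -- convenience -------------------------------------------------------
    @property
    def transcripts(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_meta["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for_stage(self, stage: str) -> list[str]:
        mask = self.sample_meta["stage"] == stage
        return list(self.sample_meta.index[mask])

    def transcript_values(self, transcript_id: str) -> pd.Series:
        if transcript_id not in self.values.columns:
            raise LookupError_(f"transcript {transcript_id!r} absent from matrix")
        return self.values[transcript_id]

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids if t in self.values.columns]
        missing = set(transcript_ids) - set(ids)
        if missing:
            raise LookupError_(f"transcripts absent from matrix: {sorted(missing)}")
        return ExpressionMatrix(self.values[ids], self.sample_meta)

    def stage_means(self) -> pd.DataFrame:
        """Mean FPKM per stage (stages x transcripts)."""
        return self.values.groupby(self.sample_meta["stage"]).mean()

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Rows = transcripts, columns = <stage>_<replicate> samples."""
        self.values.T.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path, sample_meta: pd.DataFrame | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.T, sample_meta)
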