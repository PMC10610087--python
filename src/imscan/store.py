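"""Hierarchical chunked-array datastore (zarr layout) for pipeline results.

One store per analysis; groups mirror the pipeline stages::

    blocks/<kind>      pair-block table (one array per column)
    windows/           window metadata
    tallies/<key>      folded bSFS tally + kmax/scope attrs
    grids/<key>        log-pmf matrix + grid axes/fixed attrs
    gridsearch/<key>   ln CL surfaces + best indices
    scan/<key>         per-window scan table

Everything round-trips through plain zarr arrays and JSON attrs; `query`
exports any table as TSV/BED.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from imscan.demography import KmaxSpec, Model
from imscan.inference import GridSpec, LikelihoodGrid
from imscan.tally import BsfsTally


class DataStore:
    def __init__(self, path: str, mode: str = "a"):
        import zarr

        self.path = str(path)
        self.root = zarr.open_group(self.path, mode=mode)

    # ------------------------------------------------------------------
    # generic tables
    # ------------------------------------------------------------------
    def save_table(self, key: str, df: pd.DataFrame) -> None:
        g = self.root.require_group(key)
        g.attrs["columns"] = list(df.columns)
        string_cols = {}
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "UO":
                # string dtypes have no stable zarr v3 spec; keep them as
                # JSON attributes (tables here are small metadata tables)
                string_cols[col] = [str(v) for v in vals]
            else:
                g.create_array(col, data=vals, overwrite=True)
        g.attrs["string_columns"] = string_cols

    def load_table(self, key: str) -> pd.DataFrame:
        g = self.root[key]
        cols = g.attrs["columns"]
        string_cols = g.attrs.get("string_columns", {})
        out = {}
        for c in cols:
            out[c] = np.array(string_cols[c]) if c in string_cols else np.asarray(g[c])
        return pd.DataFrame(out)

    # ------------------------------------------------------------------
    # tallies
    # ------------------------------------------------------------------
    def save_tally(self, key: str, tally: BsfsTally) -> None:
        arr = self.root.create_array(f"tallies/{key}", data=tally.counts,
                                     overwrite=True)
        arr.attrs.update(dict(kmax=list(tally.kmax.caps), scope=tally.scope,
                              n_blocks_retained=tally.n_blocks_retained,
                              n_fgv_excluded=tally.n_fgv_excluded))

    def load_tally(self, key: str) -> BsfsTally:
        arr = self.root[f"tallies/{key}"]
        a = arr.attrs
        return BsfsTally(counts=np.asarray(arr), kmax=KmaxSpec(*a["kmax"]),
                         scope=a["scope"], n_blocks_retained=a["n_blocks_retained"],
                         n_fgv_excluded=a["n_fgv_excluded"])

    def save_window_tallies(self, key: str, tallies: list[BsfsTally]) -> None:
        counts = np.stack([t.counts for t in tallies])
        arr = self.root.create_array(f"tallies/{key}", data=counts, overwrite=True)
        arr.attrs.update(dict(kmax=list(tallies[0].kmax.caps), scope="windows",
                              n_fgv=[t.n_fgv_excluded for t in tallies]))

    def load_window_tallies(self, key: str) -> list[BsfsTally]:
        arr = self.root[f"tallies/{key}"]
        kmax = KmaxSpec(*arr.attrs["kmax"])
        n_fgv = arr.attrs["n_fgv"]
        return [BsfsTally.from_array(c, kmax, scope="windows", n_fgv_excluded=f)
                for c, f in zip(np.asarray(arr), n_fgv)]

    # ------------------------------------------------------------------
    # likelihood grids
    # ------------------------------------------------------------------
    def save_grid(self, key: str, grid: LikelihoodGrid) -> None:
        arr = self.root.create_array(f"grids/{key}", data=grid.log_pmfs,
                                     overwrite=True)
        spec = grid.spec
        arr.attrs.update(dict(
            model=spec.model.value,
            axes_names=list(spec.axes),
            axes_values=[list(map(float, v)) for v in spec.axes.values()],
            fixed=json.dumps(spec.fixed),
            mu=spec.mu, block_length=spec.block_length,
            kmax=list(spec.kmax.caps),
            errors=json.dumps({str(k): v for k, v in grid.errors.items()}),
        ))

    def load_grid(self, key: str) -> LikelihoodGrid:
        arr = self.root[f"grids/{key}"]
        a = arr.attrs
        spec = GridSpec(
            model=Model(a["model"]),
            axes={n: np.array(v) for n, v in zip(a["axes_names"], a["axes_values"])},
            fixed=json.loads(a["fixed"]), mu=a["mu"],
            block_length=a["block_length"], kmax=KmaxSpec(*a["kmax"]),
        )
        return LikelihoodGrid(spec=spec, log_pmfs=np.asarray(arr),
                              errors={int(k): v for k, v in
                                      json.loads(a["errors"]).items()})

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def export_tsv(self, key: str, path: str) -> None:
        self.load_table(key).to_csv(path, sep="\t", index=False)

    def export_bed(self, key: str, path: str,
                   cols: tuple[str, str, str] = ("sequence", "start", "end")) -> None:
        df = self.load_table(key)
        df[list(cols)].to_csv(path, sep="\t", index=False, header=False)

    def keys(self, group: str = "") -> list[str]:
        g = self.root[group] if group else self.root
        return sorted(set(g.group_keys()) | set(g.array_keys()))


def blocks_to_frame(blocks) -> pd.DataFrame:
    """Pair-block list -> flat table (runs are JSON-encoded)."""
    return pd.DataFrame([
        dict(sequence=b.sequence, start=b.start, end=b.end,
             sample_a=b.pair[0], sample_b=b.pair[1], pair_type=b.pair_type,
             het_b=b.counts[0], het_a=b.counts[1], het_ab=b.counts[2],
             fixed_diff=b.counts[3], n_missing=b.n_missing,
             n_multiallelic=b.n_multiallelic, is_fgv=b.is_fgv,
             runs=json.dumps([list(r) for r in b.runs]))
        for b in blocks
    ])


def frame_to_blocks(df: pd.DataFrame):
    from imscan.blocks import PairBlock

    out = []
    for row in df.itertuples(index=False):
        out.append(PairBlock(
            sequence=str(row.sequence), pair=(str(row.sample_a), str(row.sample_b)),
            start=int(row.start), end=int(row.end),
            runs=tuple(tuple(r) for r in json.loads(row.runs)),
            counts=(int(row.het_b), int(row.het_a), int(row.het_ab),
                    int(row.fixed_diff)),
            n_missing=int(row.n_missing), n_multiallelic=int(row.n_multiallelic),
            pair_type=str(row.pair_type)))
    return out
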