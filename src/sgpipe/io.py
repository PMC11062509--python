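"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: CSV for weather/anthesis/labels/trajectories/
scores, uncompressed VCF for genotypes (read back through cyvcf2), GeoJSON
for plot maps (pixel coordinates) and single-band TIFF rasters per band per
flight date.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .types import BANDS, BandStack, GenotypeMatrix, PlotMap, Rect, SITrajectory


# ---------------------------------------------------------------------------
# CSV tables


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["date", "tmean"]].to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df[["date", "tmean"]]


def write_anthesis_csv(anthesis: pd.Series, path) -> None:
    df = anthesis.rename("anthesis_date").to_frame()
    df.index.name = "accession"
    df["anthesis_date"] = pd.to_datetime(df["anthesis_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path)


def read_anthesis_csv(path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["anthesis_date"])
    return pd.Series(
        df["anthesis_date"].values, index=pd.Index(df["accession"], name="accession"),
        name="anthesis",
    )


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index_label="accession")


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="accession")


def write_trajectory_csv(traj: SITrajectory, path) -> None:
    """Long-format `plot_id,date,index,value`; the anthesis flight is the
    earliest date in the file."""
    out = traj.values.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_trajectory_csv(path) -> SITrajectory:
    df = pd.read_csv(path, parse_dates=["date"])
    return SITrajectory(values=df, anthesis_date=df["date"].min())


def write_rsgs_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_rsgs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# VCF + label sheet


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal uncompressed VCF with diploid GT calls."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sgpipe\n")
        for c in pd.unique(geno.chrom):
            length = int(geno.pos_bp[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(geno.accessions)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        ref = np.asarray(geno.ref)
        alt = np.asarray(geno.alt)
        for j in range(geno.n_snp):
            calls = "\t".join(gt_map[int(d)] for d in geno.dosages[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos_bp[j]}\t{geno.snp_ids[j]}\t"
                f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path, labels: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (biallelic sites only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = np.array(vcf.samples)
    chrom, pos, ids, ref, alt, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID if v.ID else f"s{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        dos = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, -1)))
        rows.append(dos.astype(np.int8))
    vcf.close()
    dosages = np.stack(rows, axis=1) if rows else np.empty((len(accessions), 0), np.int8)
    if labels is None:
        labels = pd.DataFrame(
            {"flowering_class": "MF", "era": "unknown", "region": "unknown", "group": "unknown"},
            index=pd.Index(accessions, name="accession"),
        )
    return GenotypeMatrix(
        dosages=dosages,
        chrom=np.array(chrom),
        pos_bp=np.array(pos, dtype=np.int64),
        snp_ids=np.array(ids),
        accessions=accessions,
        labels=labels,
        ref=np.array(ref),
        alt=np.array(alt),
    )


# ---------------------------------------------------------------------------
# rasters and plot maps


def write_band_tiffs(stack: BandStack, outdir, prefix: str | None = None) -> list[Path]:
    """One float32 TIFF per band: `<date>_<band>.tif`."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or stack.date.strftime("%Y%m%d")
    paths = []
    for b in BANDS:
        p = outdir / f"{prefix}_{b}.tif"
        tifffile.imwrite(p, stack.bands[b].astype(np.float32))
        paths.append(p)
    return paths


def read_band_tiffs(outdir, date, panel_region: Rect, prefix: str | None = None) -> BandStack:
    import tifffile

    outdir = Path(outdir)
    date = pd.Timestamp(date)
    prefix = prefix or date.strftime("%Y%m%d")
    bands = {}
    for b in BANDS:
        p = outdir / f"{prefix}_{b}.tif"
        if not p.exists():
            raise InvalidArgumentError(f"missing band raster {p}")
        bands[b] = np.asarray(tifffile.imread(p), dtype=float)
    return BandStack(bands=bands, date=date, panel_region=panel_region)


def write_plot_geojson(plot_map: PlotMap, path) -> None:
    """GeoJSON FeatureCollection of plot rectangles in (col, row) pixel
    coordinates."""
    features = []
    for row in plot_map.plots.itertuples(index=False):
        r0, c0, r1, c1 = int(row.row0), int(row.col0), int(row.row1), int(row.col1)
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": row.plot_id},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[c0, r0], [c1, r0], [c1, r1], [c0, r1], [c0, r0]]],
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_plot_geojson(path) -> PlotMap:
    from shapely.geometry import shape

    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        poly = shape(feat["geometry"])
        c0, r0, c1, r1 = poly.bounds
        rows.append((feat["properties"]["plot_id"], int(r0), int(c0), int(r1), int(c1)))
    return PlotMap(pd.DataFrame(rows, columns=["plot_id", "row0", "col0", "row1", "col1"]))


def write_ground_truth_json(path, **payload) -> None:
    """Dump scene ground truth (gains, rates, architecture, ...) as JSON."""

    def default(o):
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.Series):
            return {str(k): v for k, v in o.items()}
        if isinstance(o, pd.Timestamp):
            return o.strftime("%Y-%m-%d")
        raise TypeError(f"unserialisable {type(o)}")

    Path(path).write_text(json.dumps(payload, default=default, indent=1))
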