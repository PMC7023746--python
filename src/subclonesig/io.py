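"""Reading and writing the standard formats around the pipeline.

VCF 4.x for substitutions and indels (via cyvcf2 / pysam), BEDPE for
rearrangements, TSV for catalogs (channel label first column, one column
per sample — small enough that human inspection matters), YAML for the
lineage manifest, and JSON run-records capturing seeds and parameters.
"""

from __future__ import annotations

import json
import logging
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from cyvcf2 import VCF

from .catalog import Catalog, MutationRecord, fetch_reference
from .channels import ChannelScheme
from .errors import CatalogParseError, InvalidInputError, VcfParseError
from .qc import LineageManifest

log = logging.getLogger("subclonesig")

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "rtype",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _typed_record(
    sample_id: str, chrom: str, pos: int, ref: str, alt: str,
    vaf: Optional[float], depth: Optional[int],
) -> Optional[MutationRecord]:
    """Type one decomposed VCF allele into a MutationRecord (or None to skip)."""
    if len(ref) == 1 and len(alt) == 1:
        mclass, r, a, p = "SBS", ref, alt, pos
    elif len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        mclass, r, a, p = "DBS", ref, alt, pos
    elif len(ref) > len(alt) and ref.startswith(alt):
        mclass, r, a, p = "DEL", ref[len(alt):], "", pos + len(alt)
    elif len(alt) > len(ref) and alt.startswith(ref):
        mclass, r, a, p = "INS", "", alt[len(ref):], pos + len(ref)
    else:
        log.info("skipping complex allele %s:%d %s>%s", chrom, pos, ref, alt)
        return None
    return MutationRecord(
        sample_id=sample_id, chrom=chrom, pos=p, ref=r, alt=a,
        mclass=mclass, vaf=vaf, depth=depth,
    )


def _sample_scalar(variant, field: str, sample_index: int):
    arr = variant.format(field)
    if arr is None:
        val = variant.INFO.get(field)
        return None if val is None else float(val)
    val = np.asarray(arr).ravel()[sample_index]
    try:
        val = float(val)
    except (TypeError, ValueError):
        return None
    if np.isnan(val) or val < 0:  # missing FORMAT values surface as NaN / -1
        return None
    return val


def read_variants(vcf_path: str, sample_id: Optional[str] = None) -> List[MutationRecord]:
    """Read somatic calls from a VCF into typed mutation records.

    Multi-allelic rows are decomposed; adjacent same-sample SNVs are
    merged into one doublet record (logged); AF and DP are taken from the
    FORMAT fields when present, else from INFO. ``sample_id`` defaults to
    the single sample named in the VCF (or the file stem).
    """
    try:
        vcf = VCF(vcf_path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else str(vcf_path)
    si = vcf.samples.index(sample_id) if sample_id in vcf.samples else 0

    raw: List[MutationRecord] = []
    for v in vcf:
        vaf = _sample_scalar(v, "AF", si)
        depth = _sample_scalar(v, "DP", si)
        depth = int(depth) if depth is not None else None
        for alt in v.ALT:
            rec = _typed_record(sample_id, v.CHROM, v.POS, v.REF, alt, vaf, depth)
            if rec is not None:
                raw.append(rec)
    vcf.close()
    return merge_adjacent_snvs(raw)


def merge_adjacent_snvs(records: Sequence[MutationRecord]) -> List[MutationRecord]:
    """Merge same-sample SNVs at adjacent positions into doublet records."""
    snvs = sorted(
        (r for r in records if r.mclass == "SBS"),
        key=lambda r: (r.sample_id, r.chrom, r.pos),
    )
    other = [r for r in records if r.mclass != "SBS"]
    merged: List[MutationRecord] = []
    i = 0
    while i < len(snvs):
        a = snvs[i]
        if (
            i + 1 < len(snvs)
            and snvs[i + 1].sample_id == a.sample_id
            and snvs[i + 1].chrom == a.chrom
            and snvs[i + 1].pos == a.pos + 1
        ):
            b = snvs[i + 1]
            log.info(
                "merging adjacent SNVs %s:%d/%d into a doublet for %s",
                a.chrom, a.pos, b.pos, a.sample_id,
            )
            vafs = [x for x in (a.vaf, b.vaf) if x is not None]
            merged.append(
                MutationRecord(
                    sample_id=a.sample_id, chrom=a.chrom, pos=a.pos,
                    ref=a.ref + b.ref, alt=a.alt + b.alt, mclass="DBS",
                    vaf=sum(vafs) / len(vafs) if vafs else None,
                    depth=a.depth if a.depth is not None else b.depth,
                )
            )
            i += 2
        else:
            merged.append(a)
            i += 1
    return sorted(merged + other, key=lambda r: (r.sample_id, r.chrom, r.pos))


def write_vcf(
    records: Sequence[MutationRecord],
    path: str,
    reference,
    contig_lengths: Optional[Dict[str, int]] = None,
    sample_id: Optional[str] = None,
) -> None:
    """Write substitution/indel records for one sample as VCF 4.2.

    Indel records (which store the event sequence only) are re-anchored
    on the preceding reference base, as VCF requires.
    """
    recs = [r for r in records if r.mclass in ("SBS", "DBS", "INS", "DEL")]
    if sample_id is None:
        sample_id = recs[0].sample_id if recs else "SAMPLE"
    header = pysam.VariantHeader()
    contigs = dict.fromkeys(r.chrom for r in recs)
    for c in contigs:
        length = (contig_lengths or {}).get(c)
        if length is None:
            try:
                length = len(reference[c])
            except (TypeError, KeyError):
                length = 2**29
        header.add_line(f"##contig=<ID={c},length={length}>")
    header.formats.add("AF", 1, "Float", "Variant allele fraction")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(recs, key=lambda x: (x.chrom, x.pos)):
            if r.mclass in ("SBS", "DBS"):
                pos1, ref, alt = r.pos, r.ref, r.alt
            else:
                anchor_pos = r.pos - 1
                if anchor_pos < 1:
                    raise InvalidInputError(
                        f"indel at {r.chrom}:{r.pos} has no anchor base"
                    )
                anchor = fetch_reference(reference, r.chrom, anchor_pos, anchor_pos)
                if r.mclass == "DEL":
                    pos1, ref, alt = anchor_pos, anchor + r.ref, anchor
                else:
                    pos1, ref, alt = anchor_pos, anchor, anchor + r.alt
            rec = out.new_record(
                contig=r.chrom, start=pos1 - 1, alleles=(ref, alt)
            )
            rec.samples[sample_id]["AF"] = (
                float(r.vaf) if r.vaf is not None else None
            )
            rec.samples[sample_id]["DP"] = (
                int(r.depth) if r.depth is not None else None
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def write_bedpe(records: Sequence[MutationRecord], path: str) -> None:
    """Write rearrangement records as 10-column BEDPE plus an rtype column."""
    rows = []
    for i, r in enumerate(records):
        if r.mclass != "REARR":
            continue
        if r.rtype == "translocation":
            chrom2, start2 = "chrOther", 0
        else:
            chrom2, start2 = r.chrom, r.pos - 1 + int(r.size_bp)
        rows.append(
            [r.chrom, r.pos - 1, r.pos, chrom2, start2, start2 + 1,
             f"{r.sample_id}_rearr{i}", ".", "+", "-", r.rtype]
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedpe(path: str, sample_id: str = "SAMPLE") -> List[MutationRecord]:
    """Read rearrangements from BEDPE (rtype in column 11)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS,
                     comment="#", dtype={"chrom1": str, "chrom2": str})
    out = []
    for _, row in df.iterrows():
        rtype = str(row["rtype"])
        if rtype == "translocation" or row["chrom1"] != row["chrom2"]:
            size = None
            rtype = "translocation"
        else:
            size = int(row["start2"]) - int(row["start1"])
        out.append(
            MutationRecord(
                sample_id=sample_id, chrom=str(row["chrom1"]),
                pos=int(row["start1"]) + 1, ref="A", alt="T",
                mclass="REARR", rtype=rtype, size_bp=size,
            )
        )
    return out


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def write_catalog(catalog: Catalog, path: str) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index_label="channel")


def read_catalog(path: str, scheme: ChannelScheme) -> Catalog:
    """Read a catalog TSV; labels must match ``scheme`` exactly (any order)."""
    df = pd.read_csv(path, sep="\t", index_col="channel")
    unknown = set(df.index) - set(scheme.labels)
    if unknown:
        raise CatalogParseError(
            f"labels not in scheme {scheme.name}: {sorted(unknown)[:5]}"
        )
    if set(df.index) != set(scheme.labels):
        raise CatalogParseError(f"catalog is missing channels of {scheme.name}")
    df = df.reindex(list(scheme.labels))
    values = df.to_numpy()
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise CatalogParseError("catalog cells must be integers")
    return Catalog(scheme, list(df.columns), values.astype(np.int64))


# ---------------------------------------------------------------------------
# manifest + run records
# ---------------------------------------------------------------------------

def write_manifest(manifest: LineageManifest, path: str) -> None:
    doc = {
        "grandparent": manifest.grandparent_id,
        "samples": [
            *({"id": p, "role": "parent"} for p in manifest.parents),
            *(
                {
                    "id": s,
                    "role": "subclone",
                    "parent": manifest.parent_of(s),
                    "condition": manifest.condition.get(s, ""),
                }
                for s in manifest.subclones
            ),
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str) -> LineageManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    parents: List[str] = []
    children: Dict[str, List[str]] = {}
    condition: Dict[str, str] = {}
    for entry in doc.get("samples", []):
        role = entry.get("role")
        if role == "parent":
            parents.append(entry["id"])
            children.setdefault(entry["id"], [])
        elif role == "subclone":
            children.setdefault(entry["parent"], []).append(entry["id"])
            if entry["parent"] not in parents:
                parents.append(entry["parent"])
            if entry.get("condition"):
                condition[entry["id"]] = entry["condition"]
        elif role not in (None, "grandparent"):
            raise InvalidInputError(f"unknown manifest role {role!r}")
    return LineageManifest(
        grandparent_id=doc["grandparent"],
        parents=parents,
        children=children,
        condition=condition,
    )


def write_run_record(path: str, **params) -> None:
    """JSON run-record: parameters, seeds and package version of a run."""
    from . import __version__

    record = {"package": "subclonesig", "version": __version__, **params}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
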