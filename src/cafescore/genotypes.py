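"""The in-memory genotype container and its file formats.

``GenotypeMatrix`` holds a participants × variants dosage matrix (dosage of a
counted allele in [0, 2], ``NaN`` for missing) together with per-variant
metadata: chromosome, 1-based position, counted allele, other allele, counted
allele frequency, and imputation quality.

Two interchange formats are supported: a tab-delimited dosage matrix (samples
as rows) paired with a variant-metadata table, and VCF with a ``DS`` FORMAT
field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a0", "freq", "impq"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus variant metadata.

    Attributes
    ----------
    samples : list of str
        Participant identifiers (row order of ``dosage``).
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, a1, a0, freq,
        impq``; ``a1`` is the counted (dosage) allele.
    dosage : numpy.ndarray, shape (n_samples, n_variants)
        Counted-allele dosage in [0, 2]; NaN marks a missing call.
    """

    samples: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        if not self.variants["id"].is_unique:
            raise ValueError("variant IDs must be unique")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0.0) < -1e-9 or \
               np.nanmax(self.dosage, initial=0.0) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to the nearest integer genotype (NaN preserved)."""
        out = np.round(self.dosage)
        return out

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to the masked samples/variants."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None \
            else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_variants, bool) if variant_mask is None \
            else np.asarray(variant_mask, bool)
        samples = [s for s, keep in zip(self.samples, smask) if keep]
        return GenotypeMatrix(samples=samples,
                              variants=self.variants.loc[vmask].reset_index(drop=True),
                              dosage=self.dosage[np.ix_(smask, vmask)].copy())

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant ID."""
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant '{variant_id}' not present in genotype matrix")
        return self.dosage[:, idx[0]]

    # ------------------------------------------------------------------ TSV

    def write_tsv(self, dosage_path, variants_path) -> None:
        df = pd.DataFrame(self.dosage, columns=self.variants["id"].tolist())
        df.insert(0, "participant_id", self.samples)
        df.to_csv(dosage_path, sep="\t", index=False, float_format="%.6g")
        self.variants.to_csv(variants_path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, dosage_path, variants_path) -> "GenotypeMatrix":
        df = pd.read_csv(dosage_path, sep="\t")
        variants = pd.read_csv(variants_path, sep="\t")
        samples = df["participant_id"].astype(str).tolist()
        dosage = df.drop(columns=["participant_id"]).to_numpy(float)
        ids = list(df.columns[1:])
        known = set(variants["id"].astype(str))
        missing = [v for v in ids if v not in known]
        if missing:
            raise ValueError(
                f"variant table is missing dosage columns: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        variants = variants.set_index("id").loc[ids].reset_index()
        return cls(samples=samples, variants=variants, dosage=dosage)

    # ------------------------------------------------------------------ VCF

    def write_vcf(self, path) -> None:
        """Write an uncompressed VCF with GT (hard call) and DS fields."""
        lines = ["##fileformat=VCFv4.2",
                 "##source=cafescore",
                 '##INFO=<ID=IMPQ,Number=1,Type=Float,Description="Imputation quality">',
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                 '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">']
        for chrom in pd.unique(self.variants["chrom"]):
            sub = self.variants[self.variants["chrom"] == chrom]
            lines.append(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(str(s) for s in self.samples))
        hard = self.hard_calls()
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, var in self.variants.iterrows():
            fields = [str(var["chrom"]), str(int(var["pos"])), str(var["id"]),
                      str(var["a0"]), str(var["a1"]), ".", "PASS",
                      f"IMPQ={var['impq']:.4f}", "GT:DS"]
            col = self.dosage[:, j]
            hcol = hard[:, j]
            calls = []
            for d, h in zip(col, hcol):
                if np.isnan(d):
                    calls.append("./.:.")
                else:
                    calls.append(f"{gt_map[int(h)]}:{d:.4f}")
            lines.append("\t".join(fields + calls))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_vcf(cls, path) -> "GenotypeMatrix":
        """Read a VCF, preferring the DS dosage field, falling back to GT.

        Uses cyvcf2 when importable; otherwise a minimal text parser for
        uncompressed VCFs (sufficient for the fixed schema written by
        :meth:`write_vcf`).
        """
        try:
            import cyvcf2
        except ImportError:
            return cls._read_vcf_text(path)
        vcf = cyvcf2.VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, a1s, a0s, impqs, cols = [], [], [], [], [], [], []
        for rec in vcf:
            ids.append(rec.ID)
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            a0s.append(rec.REF)
            a1s.append(rec.ALT[0])
            impq = rec.INFO.get("IMPQ")
            impqs.append(float(impq) if impq is not None else 1.0)
            ds = rec.format("DS")
            if ds is not None:
                col = np.asarray(ds, float).reshape(-1)
                col[col < -0.5] = np.nan  # cyvcf2 encodes missing as large negatives
            else:
                gts = np.asarray(rec.gt_types, float)  # 0,1,3 = hom-ref,het,hom-alt; 2 = unknown
                col = np.where(gts == 3, 2.0, gts)
                col[np.asarray(rec.gt_types) == 2] = np.nan
            cols.append(col)
        vcf.close()
        dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
        dosage = np.clip(dosage, 0.0, 2.0)
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(dosage, axis=0) / 2.0
        variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                                 "a1": a1s, "a0": a0s, "freq": freq, "impq": impqs})
        return cls(samples=samples, variants=variants, dosage=dosage)

    @classmethod
    def _read_vcf_text(cls, path) -> "GenotypeMatrix":
        samples = []
        rows = []
        meta = {"id": [], "chrom": [], "pos": [], "a1": [], "a0": [], "impq": []}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
                info, fmt = parts[7], parts[8].split(":")
                impq = 1.0
                for kv in info.split(";"):
                    if kv.startswith("IMPQ="):
                        impq = float(kv[5:])
                ds_idx = fmt.index("DS") if "DS" in fmt else None
                gt_idx = fmt.index("GT") if "GT" in fmt else None
                col = []
                for call in parts[9:]:
                    sub = call.split(":")
                    if ds_idx is not None and sub[ds_idx] != ".":
                        col.append(float(sub[ds_idx]))
                    elif gt_idx is not None and "." not in sub[gt_idx]:
                        col.append(float(sum(int(a) for a in
                                             sub[gt_idx].replace("|", "/").split("/"))))
                    else:
                        col.append(np.nan)
                meta["id"].append(vid)
                meta["chrom"].append(chrom)
                meta["pos"].append(pos)
                meta["a0"].append(ref)
                meta["a1"].append(alt)
                meta["impq"].append(impq)
                rows.append(col)
        dosage = np.array(rows, float).T if rows else np.empty((len(samples), 0))
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(dosage, axis=0) / 2.0
        variants = pd.DataFrame({"id": meta["id"], "chrom": meta["chrom"],
                                 "pos": meta["pos"], "a1": meta["a1"],
                                 "a0": meta["a0"], "freq": freq, "impq": meta["impq"]})
        return cls(samples=samples, variants=variants, dosage=dosage)
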