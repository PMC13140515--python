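"""Bookkeeping of the shipped differential-enrichment table.

Loads the transcription of the published table (42 proteins called
significantly differentially enriched between plasma-exposed
HA-decorated and control vesicles at the adjusted (-log10) p >= 1.30
line) and reproduces the printed sign counts, then demonstrates the
set-overlap helper on the table's nascent-detection annotations.
"""

from sprcorona import load_table2, set_overlap, table2_significance_counts

table = load_table2()
counts = table2_significance_counts()
print(f"proteins at the significance line: {counts['significant_total']}")
print(f"  reduced abundance (log2fc < 0):  {counts['reduced_abundance']}")
print(f"  increased abundance (log2fc > 0): {counts['increased_abundance']}")
print(f"  never seen in nascent vesicles:   {counts['not_in_nascent']}")

detected_prev = set(table.loc[table["ev_previous"], "accession"])
detected_here = set(table.loc[table["ev_this_study"], "accession"])
overlap = set_overlap({"previous_studies": detected_prev, "this_study": detected_here})
print(
    f"\nnascent-vesicle annotations: {len(detected_prev)} from previous "
    f"studies, {len(detected_here)} from this study, "
    f"{overlap.shared[('previous_studies', 'this_study')]} shared"
)

print("\nlargest enrichments toward the HA-decorated corona:")
print(
    table.sort_values("log2fc", ascending=False)[
        ["gene", "protein_name", "log2fc", "adj_p_value"]
    ]
    .head(5)
    .to_string(index=False)
)
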