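# Flux-compilation column schema

Comma-separated, UTF-8, "." decimal point, one row per site/treatment.
Values are stored exactly as printed by their sources; typographic minus
signs are normalized to ASCII "-" at read time.  Missing cells mean the
gas was not reported — never zero.

| column | content |
| --- | --- |
| site_name | site or study label, unique within the table |
| category | one of rewetted_general, rewetted_forest, paludiculture, shallow_lake, open_bog_fen |
| subgroup | finer grouping within paludiculture (reed_grasses, vaccinium, sphagnum) or empty |
| country | country / region of the site |
| latitude, longitude | decimal degrees (converted from printed DMS at encoding time); empty when not printed |
| period | measurement period as printed |
| nutrient_status | rich, poor, mixed or unknown |
| treatment | plant community / treatment description |
| nee, ch4, n2o | flux value cells: a plain number, "a to b" (range), "v ± s" (mean ± sd) or "v ±se s" (mean ± se) |
| nee_unit, ch4_unit, n2o_unit | the source's unit string (from the compilation footnotes); required whenever the value is present |
| source | citation key of the source study |
| flags | "\|"-separated subset of: season_only (growing-season rate, excluded from annual means), review (multi-site synthesis row), co2_equivalent (footnote declares CO2-eq units), ambiguous (printed cell admits several readings) |
| note | free-text provenance note, mandatory for ambiguous rows |

Sign convention: negative = uptake by the ecosystem, positive = emission
to the atmosphere.
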