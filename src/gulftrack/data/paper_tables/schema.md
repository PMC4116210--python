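# Packaged table transcriptions

CSV transcriptions of the published satellite-tracking summary tables for
Northern Gulf of Mexico loggerheads (59 tracks, 2010–2013), used by
`gulftrack.reporting` to recompute every printed summary statistic.

## table1.csv — tagging effort and turtle size
- `site`: tagging beach (Gulf Shores AL; St Joseph Peninsula FL; Eglin AFB FL)
- `n_2010..n_2013`: transmitters deployed per year
- `ccl_mean_cm`, `ccl_sd_cm`: curved carapace length summary. The published
  table pools both Florida sites into the row carrying 96.0/6.3; the SJP row
  is blank accordingly.

## table2.csv — kernel density estimation (KDE) foraging areas, 40 rows
- `tag`: platform transmitter terminal id; `period`: F1/F2 = first/second
  foraging area of that turtle
- `first_foraging_date`, `last_foraging_date`: m/d/yyyy; `days`: foraging days
- `filtered_locations`: retained Argos fixes within the foraging period
- `daily_locations`: mean daily locations used for the KDE
- `kde50_km2`, `kde95_km2`: in-water isopleth areas
- `region`: WGoM / NGoM / WFL / SNWA / SGoM

## table3.csv — minimum convex polygon (MCP) foraging areas, 10 rows
- `site_fidelity_p`: published percentile (printed as "p>..."), 100·k/101
- `mcp_km2`: in-water MCP area

## table4.csv — centroid characteristics, 50 rows (40 KDE + 10 MCP)
- `depth_m`: bathymetry at the centroid (negative below sea level)
- `dist_to_land_km`: distance to the nearest land
- `trawl_days_fished`: summed 2011–2012 shrimp-trawl effort of the containing
  statistical subzone; blank where no layer covers the centroid (printed "N/A"
  for Mexico)
- `trawl_zone_class`: the published effort-class column (1–4)
- `jurisdiction`: a US state = within that state's submerged lands (SSL);
  a country = within that country's EEZ
- `oiled`: 1 when the centroid lies within the Deepwater Horizon surface
  oiling footprint

Transcription notes: the published table prints the tag of 129496's third MCP
as "129296"; the fixture normalizes it to 129496, which is the reading
consistent with the published per-turtle counts (44 distinct turtles, 8 in
SGoM). Tables 2 and 4 disagree on the region of turtles 106360 and 108172
(WFL vs SNWA); both are transcribed verbatim and the disagreement is flagged
by `reporting.region_disagreements`.
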