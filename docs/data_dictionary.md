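# Data dictionary

## Judgment tables (`gen_argument_judgments`, `moralargs score` input)

| column | type | meaning |
|---|---|---|
| participant_id | int/str | judge identifier |
| item_id | str | moral-issue item |
| ideology | str | liberal / conservative / other |
| answer | str | judge's own yes/no answer to the item |
| yes_harm ... yes_purity | 0/1 | kind justifies the "yes" opinion (7 kinds: harm, violence, fairness, liberty, authority, loyalty, purity) |
| no_harm ... no_purity | 0/1 | kind justifies the "no" opinion |

The colon dialect (`yes:harm`) used by public advantage-measure exports is
accepted on read and normalized to underscores.

## Advantage estimates (`score_items` output)

| column | meaning |
|---|---|
| item_id | item |
| advantage | mean judge-level HVFL advantage, in [−1, 1] |
| se | sample SD / √n (NaN for a single judge) |
| n_judges | judges scoring the item |
| advantage_liberal / advantage_conservative | ideology sub-means (NaN when no judges of that ideology) |

## Survey records (`gen_survey` output; analysis input)

| column | meaning |
|---|---|
| respondent_id | individual (grouping level of the individual random intercept) |
| item_id | issue (issue random intercept) |
| wave_year | survey wave; item_id × wave_year is the issue-wave level |
| opinion_adv | 1 = holds the HVFL-advantaged opinion, 0 = opposite, missing = neutral/omitted |
| ideology3 | liberal / moderate / conservative (7-point scale collapsed 1–3 / 4 / 5–7) |
| df_raw | raw discussion frequency (integer 0–7) |
| df_std | DF standardized over the generated sample (fits re-standardize within their estimation sample) |
| education_std, age_std, media_std | standardized continuous controls |
| woman | 0/1 |
| eth_black, eth_other | ethnicity dummies (reference: white) |
| weight | survey weight (≥ 0; generated as 1) |
| advantage | the generating item advantage (synthetic tables only) |

The truth sidecar `truth.json` echoes every `SurveyDGP` parameter,
including per-issue advantages and random-intercept SDs.

## Simulator trajectories (`SimulationResults.trajectories()` / `moralargs simulate`)

Long format: `replicate`, `t` (0..horizon), `ideology`, `freq_class`,
`prevalence` (share of the advantaged opinion in that ideology ×
frequency-class cell).
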