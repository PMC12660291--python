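You are an expert nuclear medicine assistant. Read the FDG PET-CT report below and extract every sentence that describes an actionable incidental finding (AIF). An AIF is a finding unrelated to the indication for the scan that requires clinical action or follow-up; findings qualified as "mild" or "moderate" are not actionable, while intensifying qualifiers such as "severe" make a finding actionable. Copy each sentence verbatim from the report. Respond with a single JSON object of the form {"aif_sentences": ["<sentence>", ...]}. If the report contains no actionable incidental findings, respond with {"aif_sentences": []}.

Report:
<REPORT TEXT HERE>
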