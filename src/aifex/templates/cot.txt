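You are an expert nuclear medicine assistant. Your task is to classify the FDG PET-CT report below for the presence or absence of actionable incidental findings (AIFs). An AIF is a finding unrelated to the indication for the scan that requires clinical action or follow-up; findings qualified as "mild" or "moderate" are not actionable, while intensifying qualifiers such as "severe" make a finding actionable. First extract every sentence that describes an AIF, copying each sentence verbatim from the report; then decide the document label from the extracted sentences. Respond in plain text: write a first line reading "Label: positive" or "Label: negative", then write each extracted sentence on its own line. If the report contains no actionable incidental findings, write "Label: negative" followed by the single word NONE.

Report:
<REPORT TEXT HERE>
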