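worry	worse
lament	worse
cry	worse
regret	worse
trouble	worse
distress	worse
painful	worse
gloomy	worse
fun	better
great	better
delighted	better
laugh	better
happy	better
relaxed	better
energetic	better
cheerful	better
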