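悩み	worse
心配	worse
嘆く	worse
泣く	worse
悔しい	worse
困る	worse
しんどい	worse
苦痛	worse
楽しみ	better
絶好調	better
喜ぶ	better
笑う	better
嬉しい	better
幸せ	better
のんびり	better
元気	better
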