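match_kind,pattern_or_id,bin
keyword,kavalactone,kavalactone
keyword,kava lactone,kavalactone
keyword,kavapyrone,kavalactone
keyword,chalcone,chalcone
keyword,chalconoid,chalcone
keyword,flavokavain,chalcone
keyword,flavon,flavonoid
keyword,flavan,flavonoid
keyword,cinnam,cinnamic acid
keyword,phenylpropanoid,cinnamic acid
keyword,terpen,terpene
keyword,terpinen,terpene
keyword,alkaloid,alkaloid
keyword,piperidine,alkaloid
keyword,pyrrolidine amide,alkaloid
keyword,benzenoid,benzenoid
keyword,benzene,benzenoid
keyword,phenol,benzenoid
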