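province	block
Beijing	I
Tianjin	I
Hebei	I
Shanxi	I
Shandong	I
Henan	I
Jilin	II
Inner Mongolia	II
Liaoning	II
Ningxia	II
Heilongjiang	II
Zhejiang	III
Jiangsu	III
Jiangxi	III
Anhui	III
Fujian	III
Hubei	III
Hunan	III
Guangdong	III
Shanghai	III
Hainan	IV
Chongqing	IV
Guangxi	IV
Guizhou	IV
Yunnan	IV
Tibet	IV
Shaanxi	IV
Gansu	IV
Qinghai	IV
Sichuan	IV
Xinjiang	IV
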