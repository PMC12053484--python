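>UGP_018
RRKMDDYGLNESTQNEGLHRHIIWIMPLTGDQGYFACCKAWNIEGTYDVTFLVKEYNWFPNHDPVPENGATYSWGPKSFI
SCNIYNSKGWMRNLNHSNLHYCQMWQGHIVKASMGCWAAVSWHDQGYQLNRRCLTHATWHDMWKWSGHPTKGHSVHQRFE
DAVVYEDQKQGLIDAGPDIPIWHCNNFDLGEKISTQYLLKAEQEMADCFTSETTVPWTMCSYPDDKAHNSAWLEHYHPPN
FSDPATKWIGFHIARHYWDWPHGSYENAVEFARCLRFLKAIPFFWRADRNMESYQMEQKNACAQTVTVAKPTDMNARMAA
YPHVHTLQPYSPNCTGCEYPWGQFDQCIAIGLGYFVYVSKFGWEVGMTYIRDWWTPRIDAHKLMDHWRNYMKDVENRMIP
PTGIKIKHLLWPRTEMMWRCSETFMTWIMTMHSGPHVGIRESYNNGQCFYMAATEPWFPATVKIEQWESWAERYIDGTDK
YYSGWFLYDMKMFYGATNDVPYMDVPWWEFKSNLHIAAAINEVWMMNPHIWHSWVAKTGGANLWMKHCWTCSPWVNKSSI
KQCMTDHMIEKDHFMGVQDNAIKQPYGDFKWDQKAIGPRIQSAKETRAALAAWWYQWMHEDISDPMYFLFTKCNAAPYGD
AERNPSNWEFMTTPTAKYLYVTQGYYGYMTDVTFWAMHKTHQDNMIKGPEDCNLIKQTQP
>UGP_092
VKIEYFWRGGGDPYDHLGFMAVPMCALWQPDPKYPDFNTWSNEMNRFMYLDCKDHSETKVVPACGPSSSEIYMNCKQWRN
DYLVEQPKSSECWAYKAATIGISGPFIVHDATTTAVHRIFSRKEPYGWKNHAQDSMFPMYPYVMPKYKPKMRGHHFKDHN
HLAPNVHHIRFCENYLIHATRHPPVHIPHSVIQMQMMFNEMFMWALRDNIHGSPWHQLAHALKHMWRFKQQPPRSTQPPN
DTFQHASCCQFMESGGFIFTYANIRPTQPQAGYGQHLHNTAKYLDVAWEGYRGMNRHRCSGRHEEMGCLKHWYQYKSCME
YDLHYMNNHVRLFNYIQVIDIRLTSCIIRDRVKRQHKRNMMVNMYSRMTVFHVMVLGDMMCRWCEWTHMQCSAWTAYIDA
ANSWVKYVWWFFYDNQIIWN
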